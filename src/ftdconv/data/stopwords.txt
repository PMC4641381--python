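a
about
above
after
again
all
also
an
and
any
are
as
at
be
because
been
before
being
below
between
both
but
by
can
could
did
do
does
doing
down
during
each
few
for
from
further
had
has
have
having
here
how
if
in
into
is
it
its
itself
just
more
most
no
nor
not
now
of
off
on
once
only
or
other
our
out
over
own
same
should
so
some
such
than
that
the
their
theirs
them
then
there
these
they
this
those
through
to
too
under
until
up
very
was
we
were
what
when
where
which
while
who
whom
why
will
with
would
you
your
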