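"""Over-representation analysis against GMT gene sets with a hybrid score.

The enrichment probability is the one-sided hypergeometric upper tail
P(X >= k); an EASE-style variant (discounting one hit) is available.
Terms pass with at least ``min_k`` query hits and p <= alpha, ranked by
hybrid score = (-log10 p) * fold enrichment * k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.term_id!r} has no members")


def read_gmt(path) -> List[GeneSet]:
    """Parse a GMT file: term_id <tab> description <tab> member genes."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets.append(
                GeneSet(parts[0], parts[1], frozenset(g.upper() for g in parts[2:] if g))
            )
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.members)]) + "\n")


def term_pvalue(k: int, K: int, n: int, N: int, ease: bool = False) -> float:
    """One-sided hypergeometric enrichment probability P(X >= k).

    k hits among n query genes, for a term of size K in a background of
    size N.  With ``ease=True`` one hit is discounted (DAVID's EASE
    penalization), i.e. the tail is computed at k-1.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and N >= 0):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    kk = k - 1 if ease else k
    if kk <= 0:
        return 1.0
    # sf(kk-1) = P(X >= kk)
    p = float(stats.hypergeom.sf(kk - 1, N, K, n))
    return min(max(p, 0.0), 1.0) or 5e-324


def enrichment_factor(k: int, K: int, n: int, N: int) -> float:
    """Fold enrichment (k/n) / (K/N)."""
    if n == 0 or K == 0 or N == 0:
        raise ValueError("n, K and N must be positive")
    return (k / n) / (K / N)


def hybrid_score(p: float, ef: float, k: int) -> float:
    """Single-index term score: (-log10 p) * enrichment factor * hit count."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p!r}")
    if ef < 0 or k < 0:
        raise ValueError("enrichment factor and k must be non-negative")
    if p == 1.0:
        return 0.0
    return (-math.log10(p)) * ef * k


def _bh_adjust(pvals: Sequence[float]) -> List[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top, i in enumerate(reversed(order)):
        rank = m - rank_from_top
        prev = min(prev, pvals[i] * m / rank)
        adj[i] = prev
    return adj


def enrich(
    query: Set[str],
    background: Set[str],
    sets: Sequence[GeneSet],
    min_k: int = 2,
    alpha: float = 0.05,
    ease: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Over-representation of ``query`` within ``background`` for each term.

    Results keep terms with k >= min_k and p <= alpha (adjusted p when
    ``fdr`` enables Benjamini-Hochberg), sorted by hybrid score descending
    then term_id.  Columns: term_id, term_name, k, K, n, N, p,
    enrichment_factor, hybrid_score.
    """
    query = {g.upper() for g in query}
    background = {g.upper() for g in background}
    offenders = sorted(query - background)
    if offenders:
        raise ValueError(f"query genes absent from background: {offenders}")
    n, N = len(query), len(background)
    rows = []
    for gs in sets:
        members = gs.members & background
        K = len(members)
        k = len(query & members)
        if k < min_k or K == 0:
            continue
        p = term_pvalue(k, K, n, N, ease=ease)
        ef = enrichment_factor(k, K, n, N)
        rows.append((gs.term_id, gs.term_name, k, K, n, N, p, ef))
    cols = ["term_id", "term_name", "k", "K", "n", "N", "p", "enrichment_factor"]
    df = pd.DataFrame(rows, columns=cols)
    if len(df) == 0:
        df["hybrid_score"] = pd.Series(dtype=float)
        return df
    if fdr:
        df["p"] = _bh_adjust(df["p"].tolist())
    df = df[df["p"] <= alpha].copy()
    df["hybrid_score"] = [
        hybrid_score(p, ef, k) for p, ef, k in zip(df["p"], df["enrichment_factor"], df["k"])
    ]
    df = df.sort_values(
        ["hybrid_score", "term_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
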