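"""Loaders for the small fixtures shipped with the package."""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .burden import read_variant_table


def _data_path(name: str):
    return resources.files("ftdconv.data").joinpath(name)


def load_patient_only_variants() -> pd.DataFrame:
    """Patient-only rare missense variant table (21 carrier rows)."""
    with resources.as_file(_data_path("patient_only_variants.tsv")) as p:
        return read_variant_table(p)


def load_burden_counts() -> dict:
    """Published cohort-level carrier counts for the burden comparison.

    The control carrier count is derived, not printed; see the "comment"
    key for the derivation.
    """
    return json.loads(_data_path("burden_fixture.json").read_text())
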