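import numpy as np
import pandas as pd
import pytest

from ftdconv.itraq import CHANNELS, INTENSITY_COLUMNS, default_design


def make_psms(rows):
    """Build a PSM frame from (protein, {channel: intensity}) pairs."""
    records = []
    for i, (protein, intens) in enumerate(rows):
        rec = {"peptide": f"PEP{i:04d}", "protein": protein}
        for ch in CHANNELS:
            rec[f"i{ch}"] = intens.get(ch, np.nan)
        records.append(rec)
    return pd.DataFrame(records, columns=["peptide", "protein", *INTENSITY_COLUMNS])


def uniform_psm(protein, value=100.0):
    return (protein, {ch: value for ch in CHANNELS})


@pytest.fixture
def design():
    return default_design()
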