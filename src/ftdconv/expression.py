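"""Relative expression from Ct tables with geometric-mean housekeeping
normalization, plus Mann-Whitney group comparison with significance stars."""

from __future__ import annotations

import warnings
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample_id", "group", "gene", "ct", "replicate"]

DEFAULT_HOUSEKEEPING = ("GAPDH", "ACTB")


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "gene": str})
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    return df


def normalize_expression(
    table: pd.DataFrame,
    targets: Sequence[str],
    housekeeping: Sequence[str] = DEFAULT_HOUSEKEEPING,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Housekeeping-normalized relative expression per sample and target.

    Replicate Cts are averaged per (sample, gene).  Relative quantity
    Q = efficiency ** (minCt_gene - Ct), anchored at the lowest mean Ct of
    each gene; the normalization factor is the geometric mean of the
    housekeeping quantities and the normalized level is Q_target / NF.
    Samples missing any housekeeping gene are dropped with a warning.

    Returns columns ``sample_id, group, gene, level``.
    """
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    mean_ct = (
        table.groupby(["sample_id", "group", "gene"], as_index=False)["ct"].mean()
    )
    min_ct = mean_ct.groupby("gene")["ct"].min()
    mean_ct["q"] = efficiency ** (mean_ct["gene"].map(min_ct) - mean_ct["ct"])

    hk = mean_ct[mean_ct["gene"].isin(housekeeping)]
    hk_counts = hk.groupby("sample_id")["gene"].nunique()
    complete = set(hk_counts[hk_counts == len(housekeeping)].index)
    dropped = sorted(set(mean_ct["sample_id"]) - complete)
    if dropped:
        warnings.warn(f"samples missing housekeeping measurements dropped: {dropped}")
    nf = (
        hk[hk["sample_id"].isin(complete)]
        .groupby("sample_id")["q"]
        .apply(lambda q: float(np.exp(np.log(q).mean())))
    )

    out = mean_ct[
        mean_ct["gene"].isin(targets) & mean_ct["sample_id"].isin(complete)
    ].copy()
    out["level"] = out["q"] / out["sample_id"].map(nf)
    return out[["sample_id", "group", "gene", "level"]].reset_index(drop=True)


def significance_stars(p: float) -> str:
    """'*' for p<0.05, '**' for p<0.01, '***' for p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_compare(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_max_n: int = 8,
) -> Tuple[float, str]:
    """Two-sided Mann-Whitney U test between two groups of levels.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` observations and the pooled data are tie-free;
    otherwise the normal approximation with midranks and tie correction
    (no continuity correction).  Returns (p_value, stars).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0, ""
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= exact_max_n and len(b) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    p = float(min(res.pvalue, 1.0))
    return p, significance_stars(p)
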