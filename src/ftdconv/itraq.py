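"""8-plex reporter-ion quantification and 2-SD differential significance calls.

PSM tables carry one row per peptide-spectrum match with eight reporter
channel intensities.  Only PSMs with all eight channels present and
positive are quantified.  Per PSM and comparison group the ratio is the
geometric mean of the group's channels over the geometric mean of the
control channels; the protein-level log2 ratio is the median over its
PSMs.  Significance per comparison is |log2 ratio - mean| > z * SD of
the comparison's protein log2-ratio distribution (sample SD, strict
inequality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

CHANNELS = ("113", "114", "115", "116", "117", "118", "119", "121")
INTENSITY_COLUMNS = tuple(f"i{c}" for c in CHANNELS)
CONTROL_GROUP = "control"


@dataclass(frozen=True)
class ChannelDesign:
    """Mapping of the 8 isobaric labels to sample groups.

    ``group_of`` maps every channel label (e.g. "113") to a group name;
    exactly the eight labels 113-119 and 121 must be present (there is no
    120 label in the 8-plex kit) and the control group must be non-empty.
    """

    group_of: Mapping[str, str]
    control_group: str = CONTROL_GROUP

    def __post_init__(self):
        labels = set(self.group_of)
        if labels != set(CHANNELS):
            raise ValueError(
                f"design must map exactly channels {CHANNELS}, got {sorted(labels)}"
            )
        if self.control_group not in set(self.group_of.values()):
            raise ValueError(f"control group {self.control_group!r} has no channels")

    @property
    def groups(self) -> List[str]:
        """Non-control comparison groups, in first-channel order."""
        seen = []
        for ch in CHANNELS:
            g = self.group_of[ch]
            if g != self.control_group and g not in seen:
                seen.append(g)
        return seen

    def channels_of(self, group: str) -> List[str]:
        return [ch for ch in CHANNELS if self.group_of[ch] == group]

    @classmethod
    def from_yaml(cls, path) -> "ChannelDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        group_of = {str(k): str(v) for k, v in raw["group_of"].items()}
        return cls(group_of=group_of, control_group=raw.get("control_group", CONTROL_GROUP))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"group_of": dict(self.group_of), "control_group": self.control_group},
                fh,
            )


def default_design() -> ChannelDesign:
    """Three controls (113-115), FLNC (116), GRN (117-118), VCP (119, 121)."""
    return ChannelDesign(
        group_of={
            "113": "control",
            "114": "control",
            "115": "control",
            "116": "FLNC",
            "117": "GRN",
            "118": "GRN",
            "119": "VCP",
            "121": "VCP",
        }
    )


def read_psm_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "protein": str})
    missing = [c for c in ("peptide", "protein", *INTENSITY_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table missing columns: {missing}")
    return df


def filter_psms(psms: pd.DataFrame, design: ChannelDesign) -> pd.DataFrame:
    """Retain PSMs with all eight reporter channels present and positive.

    Input row order is preserved.  Unknown intensity columns (anything
    ``i<label>`` outside the 8-plex set) are an input error.
    """
    unknown = [
        c for c in psms.columns
        if c.startswith("i") and c[1:].isdigit() and c not in INTENSITY_COLUMNS
    ]
    if unknown:
        raise ValueError(f"unknown reporter channels: {unknown}")
    intens = psms.loc[:, list(INTENSITY_COLUMNS)]
    complete = intens.notna().all(axis=1) & (intens > 0).all(axis=1)
    return psms.loc[complete].copy()


def quantify_proteins(
    psms: pd.DataFrame,
    design: ChannelDesign,
    aggregate: str = "median",
) -> pd.DataFrame:
    """Per-protein, per-comparison log2 ratios from filtered PSMs.

    For each PSM and non-control group, log2 ratio = mean of log2 group
    intensities minus mean of log2 control intensities (i.e. the log2 of
    the ratio of geometric means).  Protein log2_ratio aggregates PSM
    ratios with the median (default) or the mean.

    Returns a frame with columns ``protein, comparison, log2_ratio, n_psms``.
    """
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    intens = psms.loc[:, list(INTENSITY_COLUMNS)].to_numpy(dtype=float)
    if len(psms) and (np.isnan(intens).any() or (intens <= 0).any()):
        raise ValueError("quantify_proteins requires filtered PSMs (all channels > 0)")
    log2i = np.log2(intens) if len(psms) else intens

    ctrl_cols = [CHANNELS.index(c) for c in design.channels_of(design.control_group)]
    rows = []
    for group in design.groups:
        grp_cols = [CHANNELS.index(c) for c in design.channels_of(group)]
        if len(psms):
            psm_log2 = log2i[:, grp_cols].mean(axis=1) - log2i[:, ctrl_cols].mean(axis=1)
        else:
            psm_log2 = np.array([])
        per = pd.DataFrame({"protein": psms["protein"].to_numpy(), "lr": psm_log2})
        agg = per.groupby("protein", sort=True)["lr"].agg([aggregate, "size"])
        for protein, (lr, n) in agg.iterrows():
            rows.append((protein, group, float(lr), int(n)))
    return pd.DataFrame(rows, columns=["protein", "comparison", "log2_ratio", "n_psms"])


def call_differential(
    quants: pd.DataFrame,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Flag proteins deviating more than ``z_threshold`` SDs from the mean.

    Per comparison, mean and sample SD (ddof=1) of the protein log2
    ratios define the null band; ``significant`` is strict
    |z| > z_threshold (a protein exactly at the boundary is not called).
    ``direction`` is up/down relative to the comparison mean, "none" at
    the mean exactly.  A comparison with zero SD yields no calls and a
    warning.
    """
    quants = quants.copy()
    z = np.full(len(quants), np.nan)
    sig = np.zeros(len(quants), dtype=bool)
    direction = np.array(["none"] * len(quants), dtype=object)
    for comparison, idx in quants.groupby("comparison").groups.items():
        lr = quants.loc[idx, "log2_ratio"].to_numpy(dtype=float)
        if len(lr) < 3:
            raise ValueError(
                f"comparison {comparison!r} has {len(lr)} proteins; need >=3 for SD"
            )
        mu = lr.mean()
        sd = lr.std(ddof=1)
        if sd == 0:
            warnings.warn(f"comparison {comparison!r} has zero SD; no calls made")
            z[quants.index.get_indexer(idx)] = 0.0
            continue
        zi = (lr - mu) / sd
        pos = quants.index.get_indexer(idx)
        z[pos] = zi
        sig[pos] = np.abs(zi) > z_threshold
        direction[pos] = np.where(zi > 0, "up", np.where(zi < 0, "down", "none"))
    quants["z_score"] = z
    quants["significant"] = sig
    quants["direction"] = direction
    return quants


def significant_sets(called: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Split called quants into per-comparison significant frames."""
    out = {}
    for comparison, grp in called.groupby("comparison"):
        out[str(comparison)] = grp.loc[
            grp["significant"], ["protein", "direction", "log2_ratio", "z_score"]
        ].reset_index(drop=True)
    return out
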