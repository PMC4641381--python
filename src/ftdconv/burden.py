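"""Rare-variant carrier collapsing and allele-based case/control burden testing.

The burden test collapses each individual with at least one qualifying
variant into a single mutated allele, builds a 2x2 allele table with 2N
chromosomes per cohort, and reports a Pearson chi-squared statistic
(df=1, no continuity correction), a two-sided P value, the odds ratio
and its Woolf (log-odds) 95% confidence interval.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

COHORT_LABELS = ("patient", "control")

VARIANT_TABLE_COLUMNS = ["individual_id", "cohort", "gene", "variant_id", "maf", "domain"]


class FrequencyBand(str, enum.Enum):
    """MAF bands: rare (<1%), low-frequency (1-5%, inclusive), frequent (>5%)."""

    RARE = "rare"
    LOW_FREQUENCY = "low_frequency"
    FREQUENT = "frequent"


def classify_frequency(maf: float) -> FrequencyBand:
    """Assign a minor-allele-frequency band.

    Parameters
    ----------
    maf : float
        Minor allele frequency in [0, 1].

    Returns
    -------
    FrequencyBand
        ``RARE`` for maf < 0.01, ``LOW_FREQUENCY`` for 0.01 <= maf <= 0.05
        (both boundaries inclusive), ``FREQUENT`` for maf > 0.05.
    """
    if not np.isfinite(maf) or maf < 0.0 or maf > 1.0:
        raise ValueError(f"maf must be in [0, 1], got {maf!r}")
    if maf < 0.01:
        return FrequencyBand.RARE
    if maf <= 0.05:
        return FrequencyBand.LOW_FREQUENCY
    return FrequencyBand.FREQUENT


@dataclass(frozen=True)
class BurdenResult:
    """2x2 allele-table burden statistics for one case/control comparison."""

    case_carriers: int
    n_cases: int
    control_carriers: int
    n_controls: int
    case_freq_pct: float
    control_freq_pct: float
    chi2: float
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    or_defined: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def read_variant_table(path) -> pd.DataFrame:
    """Read a variant observation TSV with the canonical header."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "variant_id": str})
    missing = [c for c in VARIANT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    return df


def _validate_observations(obs: pd.DataFrame) -> None:
    bad = set(obs["cohort"].unique()) - set(COHORT_LABELS)
    if bad:
        raise ValueError(f"unknown cohort labels: {sorted(bad)}")
    dup = obs.duplicated(subset=["individual_id", "variant_id"])
    if dup.any():
        rows = obs.loc[dup, ["individual_id", "variant_id"]].head()
        raise ValueError(f"duplicate (individual_id, variant_id) rows, e.g.\n{rows}")


def collapse_carriers(
    obs: pd.DataFrame,
    band: FrequencyBand = FrequencyBand.RARE,
    n_controls: Optional[int] = None,
) -> Tuple[int, int]:
    """Count carriers of band-qualifying variants per cohort.

    Each individual carrying >=1 qualifying variant contributes exactly one
    mutated allele, regardless of how many qualifying variants they carry.

    When the ``maf`` column is absent or missing for a variant, MAF is
    computed cohort-internally from the control cohort as
    carriers / (2 * n_controls).  ``n_controls`` defaults to the number of
    distinct control individuals in ``obs`` (a lower bound, since
    non-carriers have no rows).

    Returns
    -------
    (case_carriers, control_carriers)
    """
    if len(obs) == 0:
        return 0, 0
    _validate_observations(obs)
    obs = obs.copy()

    if "maf" not in obs.columns:
        obs["maf"] = np.nan
    needs_maf = obs["maf"].isna()
    if needs_maf.any():
        if n_controls is None:
            n_controls = obs.loc[obs["cohort"] == "control", "individual_id"].nunique()
        ctrl_counts = (
            obs[obs["cohort"] == "control"]
            .groupby("variant_id")["individual_id"]
            .nunique()
        )
        denom = 2 * max(n_controls, 1)
        est = obs["variant_id"].map(ctrl_counts).fillna(0.0) / denom
        obs.loc[needs_maf, "maf"] = est[needs_maf]

    in_band = obs["maf"].map(lambda m: classify_frequency(float(m)) is band)
    qual = obs[in_band]
    case_carriers = qual.loc[qual["cohort"] == "patient", "individual_id"].nunique()
    control_carriers = qual.loc[qual["cohort"] == "control", "individual_id"].nunique()
    return int(case_carriers), int(control_carriers)


def burden_test(
    case_carriers: int,
    n_cases: int,
    control_carriers: int,
    n_controls: int,
) -> BurdenResult:
    """Allele-based 2x2 burden test.

    The table counts one mutated allele per carrier against the remaining
    2N - carriers reference chromosomes of each cohort (heterozygous
    carriers assumed):

        a = case carriers        b = 2*n_cases - a
        c = control carriers     d = 2*n_controls - c

    chi2 is Pearson's statistic without continuity correction; the odds
    ratio is (a*d)/(b*c) with a Woolf confidence interval
    exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).  A zero cell makes
    OR/CI undefined (``or_defined=False``); no continuity correction is
    applied silently.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("cohort sizes must be positive")
    if not (0 <= case_carriers <= n_cases) or not (0 <= control_carriers <= n_controls):
        raise ValueError("carrier counts must lie within cohort sizes")

    a = case_carriers
    b = 2 * n_cases - case_carriers
    c = control_carriers
    d = 2 * n_controls - control_carriers

    if a + c == 0 or b + d == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(
            np.array([[a, b], [c, d]]), correction=False
        )
        chi2 = float(chi2)
        p = float(min(p, 1.0))
        if chi2 == 0.0:
            p = 1.0

    if min(a, b, c, d) > 0:
        odds_ratio = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci_low = math.exp(math.log(odds_ratio) - 1.96 * se)
        ci_high = math.exp(math.log(odds_ratio) + 1.96 * se)
        or_defined = True
    else:
        odds_ratio = ci_low = ci_high = float("nan")
        or_defined = False

    return BurdenResult(
        case_carriers=a,
        n_cases=n_cases,
        control_carriers=c,
        n_controls=n_controls,
        case_freq_pct=100.0 * a / n_cases,
        control_freq_pct=100.0 * c / n_controls,
        chi2=chi2,
        p_value=p,
        odds_ratio=odds_ratio,
        ci_low=ci_low,
        ci_high=ci_high,
        or_defined=or_defined,
    )


def summarize_patient_only(obs: pd.DataFrame) -> Tuple[int, int]:
    """Summarize a patient-only variant table.

    Returns (number of distinct variant ids, number of carrier rows).
    Duplicate (individual_id, variant_id) rows are an input error.
    """
    if len(obs) == 0:
        return 0, 0
    _validate_observations(obs)
    return int(obs["variant_id"].nunique()), int(len(obs))


def variant_categories(obs: pd.DataFrame) -> dict:
    """Classify distinct variants by cohort presence.

    Returns counts of variants seen only in patients, in both cohorts
    ("shared"), only in controls, and the distinct-variant total.
    """
    out = {"patient_only": 0, "shared": 0, "control_only": 0, "total": 0}
    if len(obs) == 0:
        return out
    _validate_observations(obs)
    presence = obs.groupby("variant_id")["cohort"].agg(set)
    for cohorts in presence:
        if cohorts == {"patient"}:
            out["patient_only"] += 1
        elif cohorts == {"control"}:
            out["control_only"] += 1
        else:
            out["shared"] += 1
    out["total"] = int(len(presence))
    return out
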