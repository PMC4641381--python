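"""Seeded generators for every input the pipeline consumes.

All generators draw from an independent ``numpy.random.default_rng``
(PCG64) stream seeded from their config, so identical configs produce
byte-identical serialized outputs.  Each generator also returns truth
labels for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .burden import VARIANT_TABLE_COLUMNS
from .enrich import GeneSet
from .itraq import CHANNELS, INTENSITY_COLUMNS, ChannelDesign, default_design


# ---------------------------------------------------------------------------
# cohort variant tables


@dataclass(frozen=True)
class CohortSimConfig:
    n_cases: int
    n_controls: int
    carrier_freq_cases: float
    carrier_freq_controls: float
    n_genes: int = 1
    n_variants_per_gene: int = 200
    multi_variant_fraction: float = 0.02  # controls carrying 2-3 variants
    seed: int = 0

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        for f in (self.carrier_freq_cases, self.carrier_freq_controls,
                  self.multi_variant_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f!r} outside [0, 1]")
        if self.n_genes <= 0 or self.n_variants_per_gene <= 0:
            raise ValueError("gene and variant counts must be positive")


_AA = "ARNDCQEGHILKMFPSTWYV"


def simulate_cohort(cfg: CohortSimConfig) -> Tuple[pd.DataFrame, dict]:
    """Simulate a case/control variant-carrier table.

    Each individual independently carries >=1 variant at the cohort's
    configured frequency (heterozygous only); a configured fraction of
    control carriers holds 2-3 distinct variants to exercise carrier
    collapsing.  Per-variant MAF is computed from the generated carrier
    counts over all 2N chromosomes of both cohorts.

    Returns (table, truth) where truth holds the carrier id sets.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = []
    for g in range(cfg.n_genes):
        gene = f"G{g + 1:02d}"
        for v in range(cfg.n_variants_per_gene):
            pos = 50 + 13 * v + g
            a1, a2 = _AA[(v + g) % 20], _AA[(v + 7 * g + 3) % 20]
            pool.append((gene, f"p.{a1}{pos}{a2}", f"Ig {v % 24 + 1}"))

    rows: List[tuple] = []
    truth = {"case_carriers": set(), "control_carriers": set()}

    def emit(ids: np.ndarray, cohort: str, freq: float, multi_frac: float, key: str):
        carrier_mask = rng.random(len(ids)) < freq
        for ind in ids[carrier_mask]:
            truth[key].add(ind)
            n_var = 1
            if multi_frac > 0 and rng.random() < multi_frac:
                n_var = int(rng.integers(2, 4))
            picks = rng.choice(len(pool), size=n_var, replace=False)
            for pi in picks:
                gene, vid, dom = pool[pi]
                rows.append((ind, cohort, gene, vid, np.nan, dom))

    case_ids = np.array([f"case{i + 1:05d}" for i in range(cfg.n_cases)])
    ctrl_ids = np.array([f"ctrl{i + 1:05d}" for i in range(cfg.n_controls)])
    emit(case_ids, "patient", cfg.carrier_freq_cases, 0.0, "case_carriers")
    emit(ctrl_ids, "control", cfg.carrier_freq_controls,
         cfg.multi_variant_fraction, "control_carriers")

    table = pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS)
    chrom = 2 * (cfg.n_cases + cfg.n_controls)
    counts = table.groupby("variant_id")["individual_id"].nunique()
    table["maf"] = table["variant_id"].map(counts) / chrom
    return table, truth


# ---------------------------------------------------------------------------
# iTRAQ PSM tables


@dataclass(frozen=True)
class ItraqSimConfig:
    n_proteins: int
    psms_per_protein: int = 4
    design: ChannelDesign = field(default_factory=default_design)
    planted_common: Tuple[FrozenSet[str], float] = (frozenset(), 0.0)
    planted_unique: Mapping[str, Tuple[FrozenSet[str], float]] = field(default_factory=dict)
    planted_contra: Tuple[FrozenSet[str], float] = (frozenset(), 0.0)
    contra_groups: Tuple[str, str] = ("GRN", "VCP")
    noise_sd: float = 0.25  # log2 units per channel
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins <= 0 or self.psms_per_protein <= 0:
            raise ValueError("protein and PSM counts must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction outside [0, 1]")
        sets = [self.planted_common[0], self.planted_contra[0]] + [
            s for s, _ in self.planted_unique.values()
        ]
        seen: set = set()
        for s in sets:
            if seen & s:
                raise ValueError("planted protein sets must be disjoint")
            seen |= s
        groups = set(self.design.groups)
        if set(self.planted_unique) - groups:
            raise ValueError("planted_unique group not in design")
        if self.planted_contra[0] and not set(self.contra_groups) <= groups:
            raise ValueError("contra_groups not in design")


def protein_ids(n: int) -> List[str]:
    return [f"P{i + 1:04d}" for i in range(n)]


def simulate_itraq(cfg: ItraqSimConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an 8-channel reporter-intensity PSM table with planted effects.

    Channel intensities are lognormal around a per-protein base abundance;
    planted effects shift the affected group's channels by the configured
    log2 amount.  ``planted_common`` shifts every non-control group,
    ``planted_unique`` one group each, ``planted_contra`` shifts
    ``contra_groups`` by +effect and -effect.  A ``missing_fraction`` of
    PSMs loses one random channel.

    Returns (psm_table, truth) where truth has one row per protein x group
    with the planted log2 effect and class (common/unique/contra/null).
    """
    rng = np.random.default_rng(cfg.seed)
    proteins = protein_ids(cfg.n_proteins)
    groups = cfg.design.groups

    effects = {p: {g: 0.0 for g in groups} for p in proteins}
    classes = {p: "null" for p in proteins}
    common_set, common_eff = cfg.planted_common
    for p in common_set:
        for g in groups:
            effects[p][g] = common_eff
        classes[p] = "common"
    for g, (s, eff) in cfg.planted_unique.items():
        for p in s:
            effects[p][g] = eff
            classes[p] = "unique"
    contra_set, contra_eff = cfg.planted_contra
    ga, gb = cfg.contra_groups
    for p in contra_set:
        effects[p][ga] = contra_eff
        effects[p][gb] = -contra_eff
        classes[p] = "contra"

    group_of = [cfg.design.group_of[c] for c in CHANNELS]
    n_psm = cfg.n_proteins * cfg.psms_per_protein
    base = rng.normal(10.0, 1.0, size=cfg.n_proteins)

    prot_idx = np.repeat(np.arange(cfg.n_proteins), cfg.psms_per_protein)
    log2_mean = np.empty((n_psm, 8))
    for j, ch_group in enumerate(group_of):
        col = np.array([
            base[i] + (effects[proteins[i]].get(ch_group, 0.0)
                       if ch_group != cfg.design.control_group else 0.0)
            for i in range(cfg.n_proteins)
        ])
        log2_mean[:, j] = col[prot_idx]
    intens = 2.0 ** (log2_mean + rng.normal(0.0, cfg.noise_sd, size=(n_psm, 8)))

    if cfg.missing_fraction > 0:
        drop = rng.random(n_psm) < cfg.missing_fraction
        which = rng.integers(0, 8, size=n_psm)
        intens[drop, which[drop]] = np.nan

    psms = pd.DataFrame(intens, columns=list(INTENSITY_COLUMNS))
    psms.insert(0, "protein", [proteins[i] for i in prot_idx])
    psms.insert(0, "peptide", [f"PEP{i + 1:06d}" for i in range(n_psm)])

    truth = pd.DataFrame(
        [
            (p, g, effects[p][g], classes[p])
            for p in proteins
            for g in groups
        ],
        columns=["protein", "comparison", "log2_effect", "truth_class"],
    )
    return psms, truth


# ---------------------------------------------------------------------------
# gene-linked corpus


@dataclass(frozen=True)
class CorpusSimConfig:
    n_documents: int
    vocabulary: Tuple[str, ...]
    planted_links: Tuple[Tuple[str, str, float], ...] = ()  # (gene, term, rate)
    background_rate: float = 0.05
    n_background_genes: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_documents <= 0:
            raise ValueError("n_documents must be positive")
        if not self.vocabulary:
            raise ValueError("vocabulary must be non-empty")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate outside [0, 1]")
        for gene, term, rate in self.planted_links:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"planted rate {rate!r} outside [0, 1]")
            if rate <= self.background_rate:
                raise ValueError(
                    f"planted rate {rate} must exceed background {self.background_rate}"
                )
            if term not in self.vocabulary:
                raise ValueError(f"planted term {term!r} not in vocabulary")


def simulate_corpus(cfg: CorpusSimConfig) -> Tuple[List[dict], dict]:
    """Simulate a gene-linked bag-of-terms corpus.

    Each document is linked to one gene (cycling through planted and
    background genes).  Every vocabulary term enters a document with the
    background rate, except a planted (gene, term) pair, which co-occurs
    in that gene's documents at its planted rate.

    Returns (documents, truth) with truth mapping genes to planted terms.
    """
    rng = np.random.default_rng(cfg.seed)
    planted_by_gene: Dict[str, Dict[str, float]] = {}
    for gene, term, rate in cfg.planted_links:
        planted_by_gene.setdefault(gene.upper(), {})[term] = rate
    genes = sorted(planted_by_gene) + [
        f"BG{i + 1:02d}" for i in range(cfg.n_background_genes)
    ]

    docs = []
    for d in range(cfg.n_documents):
        gene = genes[d % len(genes)]
        planted = planted_by_gene.get(gene, {})
        tokens = []
        for term in cfg.vocabulary:
            rate = planted.get(term, cfg.background_rate)
            if rng.random() < rate:
                tokens.append(term)
        docs.append({"doc_id": f"doc{d + 1:05d}", "text": " ".join(tokens), "genes": [gene]})
    truth = {"planted": {g: sorted(t) for g, t in planted_by_gene.items()}, "genes": genes}
    return docs, truth


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass(frozen=True)
class GenesetSimConfig:
    n_genes: int
    n_sets: int
    set_size: int = 10
    planted_term_genes: FrozenSet[str] = frozenset()
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_sets <= 0 or self.set_size <= 0:
            raise ValueError("counts must be positive")


def simulate_genesets(cfg: GenesetSimConfig) -> Tuple[List[GeneSet], List[str]]:
    """Random gene sets over a synthetic background plus one planted term.

    The planted term (``T0000/planted``) contains exactly the configured
    genes; the remaining sets are uniform draws from the background.
    Returns (gene_sets, background_genes).
    """
    rng = np.random.default_rng(cfg.seed)
    background = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    universe = sorted(set(background) | {g.upper() for g in cfg.planted_term_genes})
    sets = []
    if cfg.planted_term_genes:
        sets.append(GeneSet("T0000", "planted", frozenset(
            g.upper() for g in cfg.planted_term_genes)))
    for t in range(cfg.n_sets):
        members = rng.choice(len(universe), size=min(cfg.set_size, len(universe)),
                             replace=False)
        sets.append(GeneSet(f"T{t + 1:04d}", f"random_set_{t + 1}",
                            frozenset(universe[i] for i in members)))
    return sets, universe


# ---------------------------------------------------------------------------
# qPCR Ct tables


@dataclass(frozen=True)
class QpcrSimConfig:
    group_sizes: Mapping[str, int]
    target_genes: Tuple[str, ...] = ("FLNC_long", "FLNC_short")
    housekeeping: Tuple[str, ...] = ("GAPDH", "ACTB")
    group_log2_effects: Mapping[str, float] = field(default_factory=dict)
    base_ct: float = 24.0
    noise_sd: float = 0.15  # cycles
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if not self.group_sizes or any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if self.noise_sd <= 0 or self.n_replicates <= 0:
            raise ValueError("noise_sd and n_replicates must be positive")


def simulate_qpcr(cfg: QpcrSimConfig) -> pd.DataFrame:
    """Simulate a duplicate-measurement Ct table.

    A group's log2 effect lowers the target genes' Ct by that many cycles
    (one cycle per doubling); housekeeping genes are unaffected.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for group, n in cfg.group_sizes.items():
        eff = cfg.group_log2_effects.get(group, 0.0)
        for i in range(n):
            sample = f"{group}_{i + 1:02d}"
            for gene in (*cfg.housekeeping, *cfg.target_genes):
                shift = -eff if gene in cfg.target_genes else 0.0
                for rep in range(cfg.n_replicates):
                    ct = cfg.base_ct + shift + rng.normal(0.0, cfg.noise_sd)
                    rows.append((sample, group, gene, round(float(ct), 3), rep + 1))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct", "replicate"])
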