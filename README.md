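# ftdconv

Reusable building blocks for a convergent genetics + proteomics analysis of
dementia cohorts:

- **`ftdconv.burden`** — MAF banding (rare <1%, low-frequency 1–5% inclusive,
  frequent >5%), carrier collapsing (an individual with ≥1 qualifying variant
  counts as one mutated allele), and the allele-based 2×2 burden test:
  Pearson χ² (df=1, no continuity correction), odds ratio and Woolf 95% CI
  on the table `[carriers, 2N − carriers]` per cohort.
- **`ftdconv.itraq`** — 8-plex reporter-ion quantification. PSMs must carry
  all eight channels (113–119, 121); per-PSM ratios are geometric-mean group
  over geometric-mean control channels; protein log2 ratios are the median
  over PSMs; significance is strict |z| > 2 against the per-comparison mean
  and sample SD (ddof=1).
- **`ftdconv.venn`** — partition of the three significant-protein lists into
  the 7 Venn regions with up/down/contra regulation classes (any disagreeing
  pair ⇒ contra), plus the common-coherent core and per-comparison unique sets.
- **`ftdconv.enrich`** — hypergeometric over-representation against GMT gene
  sets (EASE k−1 variant and Benjamini–Hochberg behind flags), filters
  k ≥ 2 and p ≤ 0.05, ranked by hybrid score = (−log10 p) × fold enrichment × k.
- **`ftdconv.lsi`** — latent semantic indexing over a gene-linked JSONL
  corpus: log-TF / smoothed-IDF weighting, truncated SVD, gene =
  centroid of its linked documents, cosine clipped to [0, 1], implicit
  association at ≥ 0.1; size-adjusted dataset totals and word-frequency
  rankings.
- **`ftdconv.expression`** — Ct-table relative quantification with
  geometric-mean housekeeping normalization (efficiency 2.0, min-Ct anchor)
  and two-sided Mann–Whitney U comparison (exact for tie-free groups ≤ 8,
  tie-corrected normal approximation otherwise) with significance stars.
- **`ftdconv.synthetic`** — seeded generators (NumPy `default_rng`, PCG64)
  for cohort variant tables, 8-channel PSM tables with planted
  common/unique/contra effects and lognormal noise, gene-linked corpora
  with planted gene–term co-occurrence, GMT gene sets with a planted term,
  and qPCR Ct tables. Identical configs + seeds give byte-identical outputs,
  and every generator returns truth labels for recovery testing.

All file formats are plain text: TSV tables, YAML channel designs, GMT gene
sets, JSON-lines corpora, JSON results.

## CLI

```sh
ftdconv simulate cohort --seed 1 --out sim/            # also: itraq|corpus|genesets|qpcr
ftdconv burden --variants sim/variants.tsv --band rare --n-cases 529 --n-controls 920 --out burden.json
ftdconv itraq --psms sim/psms.tsv --design sim/design.yaml --z 2 --out quants.tsv
ftdconv venn --quants quants.tsv --out venn.json
ftdconv enrich --query query.txt --background background.txt --gmt sets.gmt --min-k 2 --alpha 0.05 --out enrich.tsv
ftdconv lsi score --corpus corpus.jsonl --genes genes.txt --terms terms.txt --dim 100 --out scores.tsv
ftdconv expression --ct ct.tsv --targets FLNC_long,FLNC_short --out levels.tsv
ftdconv run --config pipeline.yaml --out out/           # simulate -> burden; simulate -> itraq -> venn -> enrich -> lsi
```

`ftdconv run` writes a `manifest.json` recording the config hash, seed and
library versions; reruns with the same config and seed are bit-identical.
A minimal `pipeline.yaml` is just `seed: 1` (all stages simulated with
defaults pinned to the analysis cut-offs: z = 2 SD, ≥2 proteins per term,
p ≤ 0.05, cosine ≥ 0.1).

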