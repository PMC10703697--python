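# ashmscan

Regulatory-genomics analyses for paired longitudinal lymphoma cohorts
(indolent FL samples paired with aggressive DHL samples from the same
patients), built to run end-to-end on synthetic data with planted,
ledgered effects.

## What it does

- **`ashmscan.simulate`** — deterministic toy genome (genes with
  exon/UTR structure, H3K27ac/H3K4me3/H3K4me1 peaks, TADs, alternating
  A/B compartments), paired FL/DHL mutation cohorts with planted
  SE-promoter enrichment, kataegis clusters, stage-dependent copy gains
  and structural-variant allele frequencies, plus expression and
  two-factor proteome matrices. Every planted effect is written to a
  truth ledger (`planted_truth.json`) so downstream recovery is testable.
- **`ashmscan.variants`** — the somatic post-filter cascade (posterior
  gate, nontumor support, masks, high-quality read support, strand bias,
  allele fraction with per-sample low-purity thresholds, nontumor depth,
  edge-of-read), with a ledger attributing each rejection to its first
  failing filter; genic-context classification and stage burden tables.
- **`ashmscan.annotation`** — interval algebra (half-open BED
  semantics), enhancer stitching (12.5 kb), rank-signal elbow
  super-enhancer calling, mark-region partitioning
  (K27ac−K4me3 / K4me3−K27ac / intersection), compartment fractions,
  strand-aware TSS distances.
- **`ashmscan.enrichment`** — anchored density profiles (TSS, mark
  regions, TAD boundaries), rainfall / kataegis detection, the 3-kb
  differential segment scan (one-sided binomial vs the genome-wide DHL
  proportion, BH-adjusted), per-peak paired Wilcoxon comparisons,
  compartment fractions of SE mutations, micro-indel summaries.
- **`ashmscan.retargeting`** — TAD gene-pair enumeration, Spearman
  correlation, central-limit rank aggregation
  (z = (R̄ − (n+1)/2) / sqrt((n²−1)/(12m)), p = Φ(z)) over the
  mean-expression and correlation lists, hypermutation annotation and
  candidate ranking.
- **`ashmscan.stats`** — exact Fisher 2×2 (full hypergeometric
  enumeration, minimum-likelihood two-sided rule), exact/approximate
  Wilcoxon signed-rank, chi-squared, Benjamini–Hochberg, SV allele
  frequency, IHC H-score, per-protein two-way ANOVA and the
  proteome-shift / tumor-suppressor association analysis.

## CLI

```sh
ashmscan simulate --outdir bundle/ --seed 1 --enrichment 10
ashmscan filter --variants bundle/variants.P1-DHL.tsv \
    --mask bundle/low_complexity_mask.bed --out kept.tsv
ashmscan enrich --bundle bundle/ --analysis scan --out scan.tsv
ashmscan er-predict --expression bundle/expression.tsv \
    --tads bundle/tads.bed --genes bundle/genome.tsv --out er.tsv
ashmscan stats fisher 0 9 6 2
ashmscan stats h-score 20 30 50
```

`--analysis` accepts `tss, marks, tad, scan, peaks, compartments,
rainfall, kataegis, indels`.

## Conventions

BED intervals are 0-based half-open; point positions (TSS, variant
positions) are 1-based; a point p overlaps [s, e) iff s ≤ p−1 < e.
Fixture bundles are plain text and byte-identical under a fixed seed.
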