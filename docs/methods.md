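# Methods

`rigmeth` re-implements, as a tested and reusable pipeline, the
methylation-array analysis used to characterize radiation-induced
gliomas (RIGs): cohort normalization of combined Illumina 450k/EPIC
intensity data, classification of tumors against pediatric
high-grade-glioma (HGG) reference methylation classes, copy-number
profiling from combined probe intensities, and the cohort statistics.
Because the underlying patient arrays are controlled-access, the package
ships a first-class synthetic-data generator that emulates the structure
of such a study with full planted ground truth; every analysis claim the
package makes is a recovery statement about that generator.

## Synthetic cohort model (`rigmeth.synth`)

The generator emulates a 32-tumor query cohort profiled alongside six
reference classes (pedGBM_RTK1, pedGBM_RTK2, pedGBM_MYCN, DMG_K27,
GBM_G34, PXA; 20 samples each), on a scaled genome of 22 autosomes of
10 Mb plus X (10 Mb) and Y (5 Mb), centromeres at 40% of each
chromosome, and focal-alteration target regions standing in for PDGFRA
(4q), CDKN2A/B (9p), MET (7q) and CDK4 (12q). Roughly one probe per
5 kb is placed uniformly at random (44,000 query probes by default),
with configurable fractions of X/Y (5%), SNP-proximal (2%),
multi-mapping (1%) and platform-private (4% 450k-only, 8% EPIC-only)
probes, plus negative (300/channel) and normalization (50/channel)
control probes.

Per probe `p` the baseline methylation fraction `b_p` is drawn from a
bimodal Beta mixture (Beta(2,12) / Beta(12,2), mixed 1:1), matching the
characteristic two-mode beta-value histogram of methylation arrays.
Each class owns 300 disjoint signature CpGs whose baseline is fixed at
0.5 for every sample; members of the owning class are shifted to
0.5 ± Δβ (default Δβ = 0.3, half hyper-, half hypomethylated). Setting
Δβ = 0 therefore makes all classes exchangeable, which the test suite
uses as a null model. Sample-level variation is Gaussian on the logit
scale (sd 0.25), which keeps betas inside (0,1) and approximates
array-level noise.

Total intensity per probe is log-normal, `T = 2^N(log2(5000), 0.5)`,
multiplied by `cn/2` inside planted copy-number segments (floored at
0.01 for homozygous deletions), and split as `M = βT`, `U = (1−β)T` —
exactly conserving `M + U = T` before batch scaling. Copy number enters
the total intensity only, never beta, keeping the methylation and
copy-number channels separable. The methylated signal is treated as the
green channel and the unmethylated as the red channel (no Type I/II
probe-design modeling). Batch structure is multiplicative per channel:
a tissue-material factor (FFPE 0.80/0.88 vs frozen 1/1) that affects
query probes only, and an array factor (EPIC 1.20/1.10 vs 450k 1/1)
that also shifts the normalization-control channel means — so dye-bias
correction removes the array scale while the material effect is left
for the linear batch model, mirroring how the two corrections divide
labor on real data.

The default plant list places the recurrent alterations of the emulated
cohort at their reported per-group frequencies: PDGFRA high-level
amplification (copy number 8) in 6/9 post-leukemia and 11/23
post-medulloblastoma tumors, CDKN2A/B homozygous deletion (4 + 17), MET
(9/32) and CDK4 (5/32) amplification, and arm-level events 1q gain
(16/32, copy number 3), 1p/6q/13q/14q loss (19/18/23/16 of 32, copy
number 1). Focal plants span the gene region plus 300 kb on each side
(800 kb total), aligned to bin boundaries; which samples carry each
event is drawn deterministically under the seed.

The clinical generator draws tumor location per primary-disease group
(hemispheric in 7/9 post-leukemia, cerebellar in 20/23
post-medulloblastoma), exponential overall survival with hazard
ln2/median (medians 8.5 and 6.0 months), an independent exponential
censoring clock calibrated to a 20% censoring fraction, log-normal
latency (medians 8 and 5 years) and a 1.28:1 male:female ratio.

What the generator does **not** emulate: Type I/II probe chemistry,
spatially correlated CpG methylation, probe-specific affinity effects,
tumor purity/ploidy, subclonality, and realistic genome-wide
rearrangement complexity. Passing recovery tests therefore demonstrate
the correctness and calibration of the pipeline's operations under the
stated noise model, not performance on real arrays.

## Normalization (`rigmeth.preprocess`)

Pipeline order is fixed: platform intersection → per-sample background
correction → per-sample dye-bias correction → log2 → per-probe batch
adjustment → back-transform → beta values → probe filtering.

* **Background**: the 5th percentile of the sample's negative controls
  (per channel) is shifted to zero. The percentile is the
  linear-interpolation quantile between order statistics (numpy's
  default), pinned for bit-reproducibility and echoed in run metadata.
  Corrected query intensities are clamped at zero because signals are
  physical; control values keep their sign so the fixed point — a
  recomputed control percentile of exactly 0 — holds.
* **Dye bias**: each channel is scaled so the mean of its normalization
  controls is exactly 10,000.
* **Batch adjustment**: per probe, an ordinary-least-squares linear
  model with additive treatment-coded effects for material
  (FFPE/frozen) and array (450k/EPIC), fitted jointly; the mean-centered
  fitted batch component is subtracted, equalizing per-probe batch-group
  means exactly while preserving the per-probe grand mean. A factor
  whose dummy columns do not extend the design's column space
  (confounded) is skipped with a warning; a level with fewer than two
  samples is an error. Methylated and unmethylated matrices are
  corrected individually, on log2(x+1) to guard zeros.
* **Beta**: `β = M / (M + U + 100)`, always in [0, 1).
* **Filtering** removes, in order: X/Y probes; SNP-proximal probes (SNP
  within 5 bp of and including the targeted CpG — the boundary is
  inclusive, distance 5 is removed and 6 kept); probes without a unique
  reference mapping at one allowed mismatch; probes absent from either
  platform. A per-rule removal report is returned; the counts sum to
  input minus retained, and filtering is idempotent.

When external data ship as beta matrices without control probes, each
correction can be disabled by config flag.

## Classification (`rigmeth.classify`)

Sample distance is `1 − r_w`, where `r_w` is the weighted Pearson
correlation with per-probe weights. "Variance-weighted" is read as
weighting by the per-probe variance (across the cohort for the distance
matrix; across the reference cohort for classification); a `uniform`
option is provided and the choice is recorded in outputs, since
variance- and inverse-variance readings are both defensible. Probe
selection takes the top-n (default 10,000) probes by standard
deviation, ties broken lexicographically.

The embedding is an exact t-SNE (theta = 0 equivalent), no input PCA,
2,500 iterations, perplexity 20, on the precomputed distance matrix,
seeded (default 42). If the cohort is smaller than 3·perplexity + 1 the
perplexity is reduced with a warning. Embedding quality is only ever
asserted via label-recovery statistics (adjusted Rand index), never via
coordinates. Hierarchical views use Ward linkage on Euclidean sample
distances and complete linkage on Euclidean probe distances.

Class assignment formalizes reading class membership off the embedding:
each query is labeled by majority vote among its k = 5 nearest
references under the weighted-correlation distance (weights from the
reference cohort's variances). A vote tie goes to the class with the
smaller mean neighbor distance, an exact tie to the lexicographically
first label; votes and mean neighbor distance are returned as
confidence surrogates. No score cutoff is applied — every query is
labeled. Because a probe that is constant across references has zero
variance weight, assignment is invariant to appending constant probes.

## Copy number (`rigmeth.cnv`)

Copy-number analysis uses the combined (methylated + unmethylated)
signal after background and dye-bias correction but **before** the
per-probe batch model. Two reasons: multiplicative batch factors are
sample-wide and cancel in the median-centered ratio below; and the
per-probe batch fit estimates group effects from the cohort, so a large
copy-number segment in one sample would bleed into its batch group's
coefficients and create arm-level artifacts in the other samples of
that group.

Autosomal filtered probes are tiled into fixed-width bins (default
200 kb), merged left-to-right until each bin holds ≥ 10 probes. Per
bin, the sample's mean probe total is compared to the median across a
copy-number-neutral reference cohort (the 120 simulated reference
samples by default; ≥ 3 required): `log2((s + ε)/(ref + ε))` with
ε = 1, then the sample's genome-wide median log2 is centered at zero,
making the profile invariant to global intensity scaling.

Segmentation minimizes within-segment squared error plus a penalty per
changepoint, solved exactly per chromosome by optimal-partitioning
dynamic programming. The default penalty is adaptive,
`3·σ̂²·ln n` per chromosome, with σ̂ estimated robustly from the median
absolute successive bin difference (scaled by 0.6745·√2) — robust to
true steps and self-calibrating across noise levels; an explicit
penalty can be supplied, and breakpoint counts are monotone
nonincreasing in it.

Calls use explicit thresholds, all config defaults echoed into every
output: focal high-level amplification at segment mean log2 ≥ 1.0 with
segment span ≤ 10% of the chromosome, homozygous deletion ≤ −1.0,
gain/loss at ±0.4; arm-level gain/loss at a length-weighted arm mean of
±0.15 with ≥ 50% of covered arm territory altered in that direction.
Genes or arms without bin coverage are "not_assessable". The
breakpoint burden is the genome-wide count of adjacent-segment
transitions with |Δ mean log2| ≥ 0.3 — a reproducible, monotone
surrogate for visually counted chromosomal breakpoints. Absolute
breakpoint counts on the scaled synthetic genome are not comparable to
counts on real genomes and are reported per cohort, not matched to any
external value.

## Cohort statistics (`rigmeth.cohortstats`)

* Fisher's exact test (two-sided) uses the classical point-probability
  rule — the sum over tables with the observed margins of probabilities
  at most the observed one (relative slack 1e−7 for float ties); it
  matches a full hypergeometric enumeration to 1e−12. Zero-margin
  tables return p = 1 with a warning.
* The two-sample t-test defaults to the Welch variant (unequal
  variances are plausible between cohorts of different size); pooled
  Student is available by flag.
* Survival uses the Kaplan–Meier product-limit estimator with a risk
  table; the median is the first time S ≤ 0.5 and is reported as "not
  reached" (None) when the curve never crosses it. Group comparison is
  the standard observed-minus-expected log-rank, chi-square with
  (groups − 1) df; the no-event degenerate case returns p = 1.
* Differential expression: per-gene one-way ANOVA, Benjamini–Hochberg
  FDR, ranking by q then p, top-n (default 100) selection, per-gene
  z-scoring and Ward sample clustering for display. Zero-variance genes
  are excluded with a warning.
* Alteration frequencies report per-group and pooled counts,
  denominators (assessable samples only), raw fractions and
  round-half-even integer percents — fractions always travel with
  percents because integer rounding of small cohorts is lossy.
  Oncoplot ordering is memo-sort: alterations by descending frequency,
  samples lexicographically by their presence pattern (ties broken by
  sample id for permutation invariance).

Null calibration of the log-rank and t tests (type-I error within 3
binomial standard deviations of α = 0.05 over 200 seeded replicates) is
part of the test suite.

## Problem sizes and determinism

The default study runs 152 samples × 44,000 probes and completes in
about half a minute on a laptop-class core; the test suite uses smaller
cohorts (18–24 samples, 2,500–12,000 probes) chosen to keep the full
suite under a few minutes while preserving the planted-recovery
margins. Every generator and every pipeline stage is deterministic
under its seed; all run outputs are byte-stable for a fixed config and
seed (floats are serialized with shortest-roundtrip repr).

## Known limitations

* No IDAT ingestion: intensity matrices are the input contract.
* No Type I/II probe-design correction or functional-normalization
  alternatives.
* The real study's probe-filter counts depend on the actual array
  manifests, dbSNP and reference-genome mappability and are documented
  as context only; the synthetic manifest reproduces the filter
  semantics, not those counts.
* No allele-specific copy number, purity/ploidy estimation, or fusion
  inference; no calibrated class-membership scores (the published
  random-forest methylation classifier is out of scope).
* Cox or multivariable survival modeling is intentionally absent.
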