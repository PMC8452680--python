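# rigmeth

Methylation-array analysis for radiation-induced glioma (RIG) cohorts.

Radiation-induced gliomas are high-grade gliomas arising inside a prior
cranial radiation field, years after treatment of a non-glial primary
malignancy (typically medulloblastoma or acute lymphoblastic leukemia).
Genome-wide DNA methylation profiling classifies such tumors against
reference methylation classes of pediatric high-grade glioma, and the
same array intensities yield copy-number profiles that reveal the
recurrent alterations of this entity — focal *PDGFRA* amplification,
*CDKN2A/B* deletion, and broad arm-level losses. `rigmeth` implements
that analysis chain as a tested, reusable pipeline, together with a
seeded synthetic-cohort generator with planted ground truth, so every
stage can be validated by recovery of known signals.

## What it computes

* **Normalization** of combined 450k/EPIC intensity matrices: platform
  intersection; per-sample, per-channel background correction (5th
  percentile of negative controls → 0) and dye-bias correction
  (normalization-control mean → 10,000); per-probe linear batch
  adjustment for material (FFPE/frozen) and array (450k/EPIC) on the
  log2 scale; beta values β = M/(M+U+100); and the four probe filters
  (X/Y, SNP-proximal, multi-mapping, platform-private).
* **Classification**: the distance between samples is 1 − r_w, the
  variance-weighted Pearson correlation over the 10,000 most variable
  CpGs; exact t-SNE (no PCA, 2,500 iterations, perplexity 20) for
  visualization, Ward/complete hierarchical clustering for heatmaps,
  and a k-nearest-reference vote (k = 5) that assigns each query tumor
  a reference methylation class.
* **Copy number**: per-bin log2 ratios of combined probe intensity
  against a diploid reference cohort (200 kb bins, ≥ 10 probes,
  median-of-references, per-sample median centering), exact penalized
  least-squares segmentation per chromosome, focal gene calls
  (high-level amplification at log2 ≥ 1 over ≤ 10% of a chromosome,
  homozygous deletion at ≤ −1), arm-level gain/loss calls (±0.15,
  ≥ 50% of the arm), and a breakpoint-burden count (adjacent-segment
  transitions with |Δlog2| ≥ 0.3).
* **Cohort statistics**: two-sided Fisher exact tests, Welch/Student t
  tests, Kaplan–Meier curves with log-rank comparison, one-way ANOVA
  differential expression with Benjamini–Hochberg FDR and top-100
  z-score clustering, and oncoplot-style alteration-frequency reports.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate the default study conditions — 32 query tumors (29 carrying
the pedGBM_RTK1 signature, 3 PXA-like) against six reference classes of
20 samples each, with the recurrent copy-number alterations planted at
their cohort frequencies — and run the full pipeline:

```python
from rigmeth.study import run_study
from rigmeth import cohortstats

result = run_study(seed=1)

print(result.assigned_labels.value_counts().to_dict())
# {'pedGBM_RTK1': 29, 'PXA': 3}

calls = result.call_matrix()
groups = result.clinical.set_index("patient_id")["primary_disease"]
report = cohortstats.alteration_frequencies(
    calls, groups.reindex(calls.index),
    co_occurrence=[("PDGFRA", "CDKN2A/B")])
f = report["frequencies"]["PDGFRA"]
print(f["count"], "/", f["denominator"], f["by_group"])
# 17 / 32 {'ALL': {'count': 6, 'denominator': 9, 'percent': 67.0},
#          'MB': {'count': 11, 'denominator': 23, 'percent': 48.0}}
```

The classifier assigns 29/32 (91%) of the query cohort to pedGBM_RTK1,
exactly recovering the planted composition, and the copy-number caller
recovers the planted *PDGFRA* amplifications in 6/9 post-ALL and 11/23
post-MB tumors (17/32 pooled). Location statistics come out the same
way: with hemispheric location drawn at the configured group
probabilities, a two-sided Fisher exact test on the simulated location
table gives p ≈ 4e-4 at this seed (the analogous test on the emulated
cohort's fixed table [[7,2],[3,20]] gives p ≈ 0.001).

The same pipeline is available from the shell as staged commands
operating on a run directory:

```sh
rigmeth simulate --seed 1 --outdir run/
rigmeth preprocess --outdir run/
rigmeth classify   --outdir run/
rigmeth cnv        --outdir run/
rigmeth stats      --outdir run/
rigmeth report     --outdir run/
```

which emit TSV matrices, BED regions, SEG segments, a Newick
dendrogram, and JSON reports, each stage alongside a metadata file
echoing its effective configuration and seed.

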