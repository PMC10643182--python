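# metabosubtype

Discovery of prognostic gene signatures and survival subtypes from
tumor-compartment expression, with a transfer classifier for external
cohorts — plus a synthetic-cohort generator with known ground truth so the
whole pipeline is testable at desk scale.

The package is aimed at analysts working with bulk RNA-seq of solid tumors
(the reference application is pancreatic ductal adenocarcinoma, PDAC) who
want to ask: *which genes, out of a candidate panel, are most consistently
associated with overall survival, and do they define molecular subtypes
with different outcomes?*

## The method

**Ensemble prognostic screen.** Training samples are randomized into
*virtual cohorts* for 20 testing cycles, each containing roughly 70% of
patients drawn without replacement. Within a cycle every gene g receives a
prognostic score — the Wald statistic `W_g = (β̂_g / se_g)²` of its
univariate Cox proportional-hazards fit (Breslow tie handling) on the
cycle's samples — and genes are ranked per cycle. A gene enters the
signature when it

1. recurs in the per-cycle top-200 ranking in at least 15 of 20 cycles, and
2. its prognostic rating (median Wald across the cycles where it ranked)
   exceeds half of the maximum rating in the screen.

The signature defines a combined prognostic rating model: the per-sample
risk score `r_s = Σ_g d_g · W̄_g · z_gs` (direction-signed, rating-weighted
sum of signature z-scores; higher = worse predicted outcome). A
latent-component partial Cox regression (sequential uncorrelated
components whose gene weights are proportional to per-gene Cox
coefficients, earlier components entering as fixed offsets) is available
for scoring genes in the context of a subset fit and for low-dimensional
risk prediction when a full multivariate Cox model cannot be fit
(genes ≫ samples).

**Subtyping and transfer.** Samples are k-means-clustered (Euclidean,
k = 2; silhouette reported for k = 2..6) on the signature-gene z-scores.
The cluster with longer Kaplan-Meier median survival is labeled M1
(lower-risk), the other M2 (high-risk). A one-hidden-layer multilayer
perceptron trained on the same z-scores transfers the labels to external
cohorts, each normalized (median-of-ratios) and z-scored within itself.

**Supporting statistics.** Kaplan-Meier estimation, two-group log-rank
tests, chi-square tests of proportions (no continuity correction),
cohort-characteristics tables, per-drug unpaired rank tests of
drug-sensitivity (AAC) with Benjamini-Hochberg adjustment.

**Synthetic cohorts.** Negative-binomial counts with sample-specific
depth; a planted set of prognostic genes whose latent expression shifts
between two hidden subtypes; Weibull proportional-hazards survival driven
by those genes; uniform censoring calibrated to a target censored
fraction. Ground truth (planted genes, coefficients, true subtype) is
returned alongside, so recovery is measurable.

## Worked example

```python
import metabosubtype as ms

expr, clin, truth = ms.generate_cohort(ms.SyntheticConfig(seed=20260101))
z = ms.zscore_genes(ms.log_transform(ms.median_of_ratios_normalize(expr)[0]))
ranking = ms.run_virtual_cohorts(z, clin, ms.VirtualCohortParams(seed=20260102))
sig = ms.select_signature(ranking)
labeled = ms.label_by_survival(
    ms.cluster_subtypes(z.restrict_genes(sig.gene_ids), k=2, seed=20260103), clin)
print(len(sig), labeled.labels.value_counts().to_dict(), labeled.logrank.p)
```

Running the numbered drivers reproduces this end to end
(`python analysis/01_simulate_cohort.py` … `05_drug_sensitivity_demo.py`);
with the seeds fixed in the scripts they print:

```
signature: 10 genes; planted-gene recurrence min=20/20 (all >= 15: True)
planted genes inside the signature: 10/10
k=2 subtypes: {'M1': 219, 'M2': 81} (M2 = 27.0% of cohort)
log-rank M1 vs M2: p = 1.6e-105
silhouette by k: {2: 0.348, 3: 0.154, 4: 0.146, 5: 0.143, 6: 0.092}
internal validation accuracy: 99.6% ± 1.0% (10-fold CV x 10 repeats, 10 input genes)
validation accuracy vs planted subtype: 99.3%
```

i.e. on a 500-gene cohort of 300 patients with 10 planted prognostic genes
the screen recovers all 10, the k=2 clustering matches the planted subtype
in 99.3% of samples, the M2 subtype has drastically shorter survival, and
a classifier trained on one cohort transfers to an independent replicate
cohort at 99% accuracy. Tables land in `results/`, raw intermediates in
`scratch/`.

There is also a CLI for ad-hoc use on TSV inputs:
`metabosubtype simulate|normalize|screen|subtype|train|classify|report|run`
(see `metabosubtype --help`); `metabosubtype run --config run.yaml`
executes the whole pipeline reproducibly from one global seed.

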