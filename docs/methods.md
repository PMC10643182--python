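# Methods

This note documents the models, the tunable parameters, the synthetic-data
design and the numerical choices made where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cox machinery

Univariate Cox proportional-hazards fits maximize the Breslow partial
likelihood by Newton-Raphson (max 50 iterations, step-halving, convergence
at |Δ log L| < 1e-9), with the standard error from the observed
information at the maximum. The fitter is vectorized across covariates:
samples are sorted once by descending time so every risk set is a prefix
sum, and all genes of a batch take their Newton steps simultaneously —
this is what makes a resampling ensemble over hundreds of genes × 20
cycles run in under a second. An optional per-sample offset enters every
linear predictor unestimated, which the latent-component model and the
component scoring mode rely on.

Degenerate inputs are a contract, not an exception: a zero-variance
covariate, or a fit that fails to converge, returns `beta = 0, wald = 0`
with a flag, so one pathological gene cannot abort an ensemble cycle.
Monotone likelihoods (risk-set separation) converge in the Δ log L sense
with a huge standard error, hence a near-zero Wald statistic — they carry
no evidence and rank last, which is the desired behavior.

Ties: Breslow's approximation, chosen as the simplest consistent
convention. Note that lifelines resolves ties with Efron's method, so the
test suite uses lifelines as an independent oracle only on tie-free data
and maximizes an explicitly written Breslow likelihood otherwise.

The Wald statistic is reported on the 1-df chi-square scale `(β/se)²`. On
this scale a half-max selection floor in the 4-5 range corresponds to a
plausible maximum of ~9-10 in a cohort of ~140, whereas reading the same
floor on the |z| scale would imply implausibly strong single-gene effects;
`wald_of(fit, scale="z")` exposes the other convention.

## Latent-component partial Cox

Component 1's gene weights are proportional to the per-gene univariate Cox
coefficients (normalized to unit length); its score is the weighted gene
sum. Each later component repeats the construction on the gene residuals
after least-squares projection (with intercept) off all previous scores,
with the previous components' combined risk contribution as a fixed
offset. Scores are therefore exactly uncorrelated in sample. K defaults
to 3; the model truncates early if no informative gene remains. The
precise variant used inside the proprietary screen this emulates is not
public; this construction follows the published latent-components idea and
is flagged as an interpretation.

## Ensemble screen

Defaults: 20 cycles, 70% of patients per cycle (without replacement,
redrawn — and logged — if a draw has fewer than 2 events), top-200
per-cycle ranking, recurrence floor 15/20, Wald floor at half the maximum
rating. Per-gene rating = median Wald across the cycles in which the gene
entered the top list (median resists single-cycle outliers); direction =
sign of the median coefficient. Ties in per-cycle ranking break by gene id
so the output is order-independent and byte-stable under a fixed seed.

Two scoring modes:

* **univariate** (default): a gene's score in any random gene subset is
  its univariate Wald on the cycle's samples, which is independent of the
  subset — so the subset loop is collapsed analytically and every gene is
  scored once per cycle. This is exactly equivalent whenever every gene is
  drawn at least once (expected draws per gene ≥ 20 under the defaults;
  the probability of a gene never being drawn is < 1e-9).
* **component**: each subset of `genes_per_draw` (default 50) genes is fit
  with a K-component partial Cox model and a member gene is scored by its
  Wald when added on top of the subset's component risk score as an
  offset; a gene's cycle score is its best across draws. This measures
  residual prognostic value in the context of co-drawn genes, at roughly
  50× the cost.

The recurrence floor 15/20 reads "recurring" as 75% consistency — strict
but robust to one unlucky cycle; it is configurable. `n_draws_per_cycle`
defaults to the number that gives each gene ≥ 20 expected draws per cycle.

**Known limitation — null behavior of the selection rule.** The half-max
floor is not a calibrated test. Under a complete null the per-gene Wald is
chi-square(1); the expected number of genes above half of the maximum of G
such draws is roughly `G · P(χ² > log G)` ≈ 10-13 for G = 500, and the
recurrence filter removes few of them because virtual cohorts share ~70%
of patients, making per-cycle Walds strongly correlated. On effect-free
synthetic cohorts the selected signature therefore averages ~10-13 genes,
not ~0 — the acceptance suite measures and reports this honestly. The
rule separates planted signal from noise by rating magnitude (planted
ratings 40-100 vs null maxima ~12 at the reference conditions), not by
controlling a false-positive rate; treat signatures from weak-signal data
accordingly.

## Normalization and standardization

Median-of-ratios size factors use as reference the genes with strictly
positive counts in every sample (geometric-mean denominator); genes with
zeros are excluded from the reference but still normalized. Size factors
are defined up to this reference: scaling one sample's column by c scales
its factor by c^(1-1/n) and everyone else's by c^(-1/n) — ratios transform
exactly by c. z-scores use the n-1 standard-deviation divisor (the
convention of the common scaling utilities; the two conventions differ
materially at small n). Constant genes z-score to all-zero rows and are
flagged rather than dropped, keeping gene indices aligned for the
classifier.

The pipeline inserts a log2(1+x) transform between normalization and
z-scoring. z-scores of raw normalized counts would be dominated by the
right skew of expression; log-scale z-scores are the standard read-out the
clustering heat-map convention assumes. The individual operations are
transform-agnostic — callers can skip the log step.

## Subtyping and classifier

k-means with Euclidean distance, 20 restarts, best inertia kept; k fixed
at 2 by default with silhouette widths for k = 2..6 reported to document
the choice. Survival labeling: longer Kaplan-Meier median survival → M1.
If neither median is defined the clusters order by mean observed time
(logged); an exact survival tie labels the smaller cluster M2 (an
arbitrary rule, warned about). The labeling operates on the partition
only, so it is idempotent.

The transfer classifier is a one-hidden-layer MLP on signature z-scores:
hidden width ⌈(G+2)/2⌉ (the average-of-layers heuristic), plain SGD with
constant learning rate 0.3, momentum 0.2, 500 epochs — the defaults of
the classic neural-network toolkits this emulates; all configurable.
Internal validation is repeated stratified 10-fold cross-validation
(default 10 repeats), reported as mean ± sd; when a class has fewer
members than folds, CV is skipped with a flag and training accuracy is
reported instead. Trained weights are stored explicitly (ReLU hidden,
logistic/softmax output), so prediction and JSON round-trips are
independent of the training backend. External cohorts must be normalized
and z-scored within themselves; input whose gene rows do not look
standardized triggers a warning, and missing model genes are an error.

## Synthetic cohorts

Each gene has latent standardized expression `x ~ N(0,1)`. A fraction
(default 0.27, matching the high-risk fraction observed in the reference
cohort) of samples is "aggressive": on planted genes they shift by
+`subtype_shift` SD when the gene increases risk and −`subtype_shift` when
it protects, so cluster structure and survival signal are coupled. Planted
coefficients alternate ±`effect_size` (mixed up/down signatures are the
norm in practice). Survival: Weibull proportional hazards by inversion,
`T = scale · (−log U / e^η)^(1/shape)` with `η = Σ β_j x_j`; shape 1.2 and
scale 24 (months) give a realistic advanced-PDAC survival scale.
Censoring is uniform on (0, c) with c solved by Brent's method so the
expected censored fraction over the realized event times hits
`censor_target` (default 0.30) — an administrative-censoring analogue.
Counts are negative binomial, `mean = depth · base_g · exp(0.5 x)`,
per-sample depth uniform in [0.5, 2], per-gene baseline log-normal
(log-mean 4.5, log-sd 1), dispersion 0.1 (variance = μ + 0.1 μ²; Poisson
limit at 0).

Default cohort dimensions follow the package's reference study conditions:
300 samples, 500 genes, 10 planted prognostic genes at effect 0.8 per SD,
subtype shift 2.0. Note the implied subtype hazard ratio is
`exp(10 · 0.8 · 2) = e¹⁶` — aggressive samples die almost immediately, so
K-M medians of the high-risk group are near zero; this makes recovery
tests sharp but is far stronger than real cohorts.

A separate `design_seed` (default 0) fixes *which* genes are planted and
their signs, while `seed` drives all sampling noise. Replicate cohorts of
one study design (same `design_seed`, different `seed`) therefore share
their prognostic genes — the setting in which training a classifier on one
cohort and validating on another is meaningful.

What the generator does **not** emulate: gene-gene correlation beyond the
planted subtype axis, tumor/stroma compartment mixing, batch effects,
covariate-dependent censoring, or clinical covariates that correlate with
subtype (age and sex are generated independently). Passing recovery tests
therefore shows the pipeline's machinery is correct and well-calibrated to
its own model, not that real cohorts will behave as cleanly.

## Statistics conventions

* Kaplan-Meier median = first event time with S(t) ≤ 0.5; infinite if the
  curve never reaches 0.5. Curves are reported at event times only.
* Chi-square tests of proportions carry no continuity correction — this is
  the convention that reproduces the reference study's printed
  contingency p-values exactly, which the acceptance suite checks.
* The per-drug sensitivity comparison is an unpaired two-sample
  Mann-Whitney U test (exact where sample sizes and ties permit,
  tie-corrected normal approximation otherwise), although the reference
  description names a signed-rank test: cell lines in two subtypes are
  unpaired, so a signed-rank test is not applicable. BH adjustment is
  applied across drugs.
* Continuous covariates in characteristics tables use the pooled-variance
  two-sample t-test; column percentages are rounded to one decimal.

## Reproducibility and problem sizes

One global pipeline seed derives a per-stage seed as the first four bytes
of SHA-256("seed:stage") mod 2³¹, so a single integer reproduces every
artifact byte for byte; the run manifest records parameters, stage seeds
and artifact checksums. The acceptance script and the Monte-Carlo tests
run at the reference conditions with 5-10 replicates per quantity (20 for
effect-free null runs in the test suite, 10 in the script) — enough to
pin the recovery rates well away from their thresholds while keeping a
full run in minutes on one CPU.
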