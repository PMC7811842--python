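# Methods

`rnaclock` models chronological age from bulk RNA-seq counts pooled
across many studies ("batches"). This note documents each stage's model
and assumptions, the synthetic-data generator used for validation, the
numerical choices, and the limitations a user should know about.

## Quality filters and age groups

Samples with fewer than two million total assigned reads are excluded
(`min_total = 2,000,000`, boundary kept): below that depth, which genes
get sampled starts to depend on depth itself. Genes with mean raw count
below 50 across the retained samples are removed (`min_mean = 50`,
boundary kept; means are computed after sample filtering). Ages are
grouped as young (< 30 y), adult (30–69 y) and older (≥ 70 y); the lower
cutoff keeps developmental expression programs out of the aging
contrast, the upper one defines the "older adult" comparison group. The
multi-modal histogram of per-sample totals is available as a diagnostic
(`qc.total_count_summary`), but the cut itself is the fixed threshold,
not data-derived. Whether the 2M boundary is inclusive is a convention;
we keep totals equal to the threshold and document rather than infer it.

## TMM normalization

For each library against a reference library, over genes positive in
both, we compute log2 expression ratios `M` and average log2 abundances
`A`, discard the extremes by rank (default 30% per tail of `M`, 5% per
tail of `A`), and average the surviving `M` values weighted by inverse
delta-method binomial variances. The reference is the library whose 75th
percentile count fraction is closest to the across-sample mean (lowest
column index on ties). Factors are rescaled to geometric mean one;
effective library size = column total × factor. Normalized expression is
`log2(pseudo + CPM)` with `pseudo = 1` and CPM computed against effective
library sizes. "Normalized counts" could also be read as raw-scale TMM
counts rather than CPM; CPM was chosen so values are comparable across
libraries of very different depth, and the choice is documented rather
than claimed. Genes with a zero in either the library or the reference
are excluded from `M`/`A` (standard convention). The implementation
agrees with the canonical R implementation to ~1e-6 on random tables
(cross-checked in the test suite), though bit-level parity is not a goal.

## Empirical-Bayes batch correction

The location/scale model per gene g, batch i, sample j:

    Y_gij = alpha_g + gamma_ig + delta_ig * eps_gij,  eps ~ N(0, sigma_g^2)

Genes are standardized by the batch-size-weighted grand mean and pooled
variance; per-batch location (`gamma_hat`, batch means) and scale
(`delta_hat`, batch variances) are estimated on standardized data; the
batch-level priors — normal for gamma (moments `gamma_bar`, `tau2`
across genes), inverse-gamma for delta (shape/scale by method of moments)
— are fitted per batch; and the coupled posterior-mean updates

    gamma* = (n_i tau2 gamma_hat + delta* gamma_bar) / (n_i tau2 + delta*)
    delta* = (2b + sum_j (Z - gamma*)^2) / (n_i + 2a - 2)

are iterated to a fixed point (max absolute change < 1e-6, at most 500
iterations; convergence typically takes < 10). The shrunken effects are
removed and the data back-transformed. Only the parametric priors are
implemented. The standardization design is intercept-only by default —
no biological covariates are protected — with an optional numeric
covariate matrix hook; with strong age–batch confounding the default
will remove real age signal (see Limitations). `mean_only` fixes
`delta* = 1` and skips shrinkage, reducing exactly to per-batch
mean-centering plus the grand mean. Genes with (numerically) zero pooled
variance are flagged and passed through unchanged. Each batch must have
at least two samples.

### Projecting new samples

`project_new_batch` appends uploaded raw counts to a reference cohort as
one extra batch, re-runs TMM → log2 CPM → correction on the union, and
returns the corrected values of the new samples in reference gene order.
Uploads must share ≥ 50% of reference genes (hard error below); missing
genes are zero-imputed with a warning when the overlap is below 90%. A
single-sample upload is allowed with a loud warning via a location-only
adjustment: the sample's standardized deviation is shrunk toward its
cross-gene mean with the scale fixed at the prior (`delta* = 1`), since
location and biology cannot be separated at n = 1. The correction
estimates the upload's batch effect from the upload's own mean, so
uploads should be batch-sized and age-diverse; a handful of samples with
a narrow age range will be partially flattened toward the reference mean.

## Gene selection and differential expression

*Variable genes*: ranked by variance of corrected log2 values across
samples, descending, ties broken by gene id. An alternative ranking by
variance of age-bin means is available behind the `age_binned` argument.

*Differential genes*: per gene, a negative-binomial log-linear model
`count ~ group + batch + offset(log effective library size)` comparing
adults to older adults. The NB dispersion is estimated per gene by
matching the Pearson chi-square statistic of a Poisson fit to its
residual degrees of freedom — a method-of-moments estimate on Pearson
residuals, floored at 1e-8, solved by bisection (the statistic is
monotone in the dispersion) — with optional shrinkage toward a
running-median mean–dispersion trend (`dispersion_shrink`). The group
effect is tested by a likelihood-ratio test between nested NB fits at
that dispersion, chi-square with 1 df; p-values are Benjamini–Hochberg
adjusted. This deliberately avoids quasi-likelihood moderation
machinery: the target is calibration (null type-I fraction ≈ the nominal
level, verified by simulation), not numeric parity with any specific
tool. If all samples share one batch the covariate is dropped with a
warning; if every batch contains only one group, group and batch are
collinear and an error names the aliasing. "Top differential" genes are
ranked by ascending p-value, ties by |log2FC| descending then gene id
(the ranking criterion is a convention; p-value was chosen and
documented). Thresholded calls use strict inequalities:
up = {log2FC > 1 and FDR < 0.05}, down mirrored.

## The random-forest clock

Features are the selected genes' corrected log2 values, standardized by
the full training set's per-gene mean and SD (constant genes dropped
with a warning). Candidate `mtry` values: 5 values from 2 to p, linearly
spaced for p < 500 and geometrically otherwise, floored to integers —
reproducing the protocol grids {2, 9, 44, 211, 1000} (p = 1000) and
{2, 26, 51, 75, 100} (p = 100). Each candidate is scored by repeated
k-fold cross-validation (default 10 folds × 2 repeats); the chosen model
is the *smallest* `mtry` whose mean RMSE is within one standard error
(SD across resamples / sqrt(resamples)) of the best — the one-SE rule,
with smaller `mtry` = weaker per-tree fitting taken as "simpler". The
final forest (default 500 trees; the desk-scale experiments in the test
suite use 60–150) is refit on all data at the chosen `mtry`, and
predictions are clamped to [0, 110] years. R² is reported as the squared
Pearson correlation of observed vs predicted (the resampling-framework
convention); the coefficient-of-determination definition is available
via `r2_mode="cod"`. Everything is deterministic given the seed: fold
assignments, bootstrap draws and importance permutations.

Feature scaling is computed on the full training set, not per CV fold —
matching the described preprocessing order — which carries a small
optimism risk in the CV estimates; it is documented rather than hidden.

*Importance*: for each tree, the MSE on its out-of-bag samples is
compared to the MSE after permuting one feature among those samples; the
per-tree increases are averaged and divided by their standard error
(mean ΔMSE / SE). Scores are left unscaled and genes with score > 1 are
flagged important. This statistic has a small positive bias under the
null (permutation adds prediction variance even for irrelevant
features), so the > 1 threshold is liberal; the test suite checks the
real-vs-shuffled-label contrast rather than a zero null rate. Trees with
no OOB samples are skipped with a warning.

## Evaluation

*Metrics*: RMSE, MAE (years) and R² (squared Pearson; NaN when the
observed ages are constant).

*Leave-one-batch-out curation*: the full pipeline (normalize → correct →
select → train) is run on all batches for a baseline, then once per
batch with that batch held out. A batch is flagged for removal only when
dropping it strictly improves RMSE, MAE and R² simultaneously. The
default is a single evaluation pass against the all-batches baseline
("each batch removed in turn"); a sequential greedy mode that
re-baselines after every removal is available (`mode="sequential"`).
Metrics come from cross-validation on the reduced data, measuring the
predictive power of the retrained model rather than held-out-batch
error.

*Learning curve*: the cohort is preprocessed once; for each size n and
repeat, n training samples are drawn uniformly without replacement, gene
selection is redone on the subset, the clock is trained (fold count
capped at n/2 for tiny subsets) and evaluated on all remaining samples;
means and SDs over repeats are reported. Defaults: sizes
{50, 100, 250, 500, 1000, 3000}, 9 repeats.

*Transfer*: a trained clock is applied to another cohort's processed
matrix; the result records whether the processing pathway matched
training (corrected vs uncorrected), since the mismatch itself is an
experimental condition. On simulated compendia where batches enroll
different age windows, a clock trained on uncorrected data collapses on
corrected data (most of its signal rides on batch signatures), while the
constant within-batch shifts mean the reverse direction mostly inflates
RMSE rather than destroying rank correlation.

## Synthetic cohorts

The generator emulates a public-data meta-analysis. Per gene and sample,

    x_gj = baseline_g + slope_g * age_j + gamma_b(j),g + delta_b(j),g * eps_gj

in log2 units, with `baseline ~ N(5, 1.5)` (log2 scale), a configurable
subset of age genes with `slope ~ N(0, 0.02)` log2/year (≈ ±2 log2 over
a century at 1 SD), batch shifts `gamma ~ N(0, batch_shift_sd)`, batch
scale multipliers `delta = exp(N(0, batch_scale_sd))` acting on the
per-gene noise `eps ~ N(0, 0.3)` — deliberately the same location/scale
form the correction assumes, so recovery is well-posed. Relative
abundances `2^x` are scaled to lognormal library sizes (ln-mean 15.5 ≈
5.4M reads, ln-SD 0.25; a configurable fraction of junk samples sits at
30–70% of the 2M QC threshold, everything else is kept ≥ 1.25× the
threshold so the filters separate them deterministically) and counts are
drawn negative-binomial with variance `mu + phi mu^2`, global dispersion
`phi = 0.05`. Ages are uniform over 0–107 y by default, with a
truncated-normal option (mean 60.5, SD 18.2) matching the pooled-cohort
shape; `batch_age_heterogeneity` makes each batch enroll from its own
random age window, emulating studies with different designs — required
to reproduce cross-pathway transfer failures, since batch markers only
predict age when batch and age are confounded. "Adversarial" batches
have their recorded ages permuted within the batch after expression is
generated, so their labels carry no signal. All draws come from one
seeded generator; identical configs give byte-identical cohorts.

What the generator does *not* emulate: gene–gene correlation beyond the
shared age/batch structure, nonlinear age trajectories, tissue-specific
expression programs, GC/length biases, or count outliers. Tests passing
on these cohorts therefore demonstrate that the pipeline recovers the
structure it models — not that real compendia satisfy that structure.

## Numerical choices and degenerate inputs

- TMM: `|log factor| < 1e-10` snapped to zero; ties in reference
  selection broken by lowest column index; zero-total columns and
  single-sample tables are errors.
- Correction: EB fixed-point tolerance 1e-6, cap 500 iterations;
  zero-variance genes passed through; inverse-gamma prior falls back to
  a flat-ish shape when the cross-gene spread of scale estimates is zero.
- Dispersion: floored at 1e-8; bisection bracket grown to 1e4.
- Clock: constant genes dropped; constant ages are an error; CV SE is 0
  with a single resample; grid values are capped at the feature count.
- Metrics: R² undefined (NaN) for constant observed or predicted
  vectors.

## Limitations

- The intercept-only correction removes age signal when age and batch
  are strongly confounded; pass age (or other biology) through the
  covariate hook when the cohort design warrants it, at the cost of
  diverging from the default protocol.
- Projection-based prediction assumes the upload resembles one coherent
  study; tiny or age-skewed uploads are over-shrunk.
- The dispersion estimator is per-gene with optional trend shrinkage; at
  very small group sizes (< ~10 per group) its calibration degrades.
- Only the random-forest regressor is built in; alternative regressors
  can be passed through the same training scaffold but are untested.
- Importance scores depend on forest size; comparing scores across
  models with different tree counts is not meaningful.
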