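# Methods

## Model

ComBat models feature *g* of sample *j* in batch *i* as

```
Y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_ijg,
eps_ijg ~ N(0, sigma_g^2)
```

`alpha_g` is the grand mean, `X` the protected-covariate design
(categorical covariates reference-coded, continuous covariates
centered), `gamma_ig` an additive and `delta_ig^2` a multiplicative
batch effect. Fitting proceeds in three steps:

1. **Standardization.** `alpha`, `beta` and per-batch means are
   estimated by least squares on the design `[batch indicators |
   covariates]`, with the grand mean defined as the batch-size-weighted
   combination of the batch coefficients. The pooled residual variance
   uses a `1/n` denominator, matching the reference formulation of the
   method; `Z = (Y - alpha - X beta) / sigma`.
2. **Empirical Bayes.** Per batch, raw effects are the batch means
   (`gamma_hat`) and batch variances (`delta2_hat`, `ddof=1`) of `Z`.
   Hyperparameters come from method of moments across features: a
   normal prior `gamma ~ N(gamma_bar, tau2)` and an inverse-gamma prior
   on `delta^2` with shape/scale `(lambda, theta)` matched to the mean
   and variance of `delta2_hat`. The conditional posterior means are
   iterated to their joint fixed point (absolute-change tolerance 1e-4,
   max 1000 iterations; an error is raised on non-convergence).
   Parametric EB only — the pathway of the reference implementation.
3. **Adjustment.** `Y* = sigma * (Z - gamma*) / sqrt(delta2*) + alpha +
   X beta`. Protected-covariate effects re-enter unchanged.

Constant features cannot be standardized; they pass through unadjusted
with a warning so column alignment is preserved. There is no
reference-batch mode: all batches shrink toward the weighted grand mean.

A consequence of the `1/n` pooled-variance convention worth knowing:
re-running the EB-off harmonization on its own output is not a strict
no-op. The second pass finds zero batch effects but rescales residuals
by exactly `sqrt((n-k)/n)` (k batch levels), because the pooled variance
of the first pass's output is computed with a different denominator than
the per-batch variances that produced it. This matches the behavior of
the established implementations and is covered by a regression test.

## Order-optimized sequential harmonization

With several batch variables, single-batch ComBat is applied
sequentially; the outcome depends on the order whenever the variables
are correlated. `opnested` enumerates all `k!` permutations (hard
ceiling of 6 variables, i.e. 720 pipelines), harmonizes under each, and
scores each candidate's **final** matrix by the total count of features
with a significant k-sample Anderson–Darling test (raw p < alpha,
default alpha 0.05, no multiple-testing correction) summed over all
batch variables. The minimum wins; ties break to the first permutation
in lexicographic enumeration order, which makes selection deterministic.
Candidates are evaluated one at a time so memory holds only the
incumbent best matrix.

The AD p-value comes from scipy's interpolated critical-value
approximation and is clipped to [0.001, 0.25]. Significance calls use
`p < alpha`, so the upper cap can never create a false positive; the
floor is recorded in every report.

## Latent grouping

Each feature is z-scored (so scores are comparable across
heterogeneously scaled features) and fitted with a two-component
univariate Gaussian mixture (EM, 10 seeded restarts, log-likelihood
tolerance 1e-6, `reg_covar` 1e-10). The selection score is the BIC of
the one-component fit minus the BIC of the two-component fit — positive
when bimodality pays for its extra parameters — tie-broken by the
standardized component separation `|mu1 - mu2| / sqrt(max variance)`.
Candidates whose smaller component holds fewer than
`min_group_fraction` (default 0.05) of samples are discarded: ComBat
needs at least two samples per level and tiny groups destabilize the EB
step. If no feature has a positive score the selector raises a
"no grouping found" error; the pipeline entry points log a warning and
fall back to plain order-optimized harmonization.

The grouping enters the pipeline in one of two ways:

- `opnested_plus_gmm`: appended to the batch list; the permutation
  search runs over `(k+1)!` orders and the grouping's own significant
  fraction is part of the selection score. Use when the hidden variable
  is believed technical.
- `opnested_minus_gmm`: appended to the protected covariates; the
  search covers only the `k!` orders of the known variables. Use when
  the hidden variable may be biological. The grouping is protected, not
  scored, but its before/after fractions are reported for comparison.

Label recovery is bounded by the mixture's Bayes error: with equal
weights and unit component variances at separation `d` the best
achievable agreement is `1 - Phi(-d/2)` (93.3% at 3 SD, 99.9% at 6 SD).
Downstream results are invariant to swapping the two component labels.

## Detection and association metrics

`count_significant` reports, per batch variable, the fraction of
features with AD p < alpha. The denominator is always the **original**
feature count, so fractions remain comparable after feature dropping.
`residualize` replaces features by OLS residuals on a covariate design
before testing, to ask how much apparent batch effect is really
clinical structure. `association_tests` runs chi-squared tests between
categorical pairs and point-biserial correlation between binary and
continuous pairs; a categorical variable with more than two levels
against a continuous covariate falls back to one-way ANOVA and is
flagged `anova_extension` (the point-biserial test is undefined there).
`drop_significant_features` removes every feature significant for at
least one batch variable and errors if that would empty the matrix.

## Survival harness

Features are z-scored and reduced by PCA (default 10 components); a cap
(`max_predictors`) limits how many scores enter the Cox model — roughly
one predictor per ten events is the intended regime. Performance is
Harrell's concordance from repeated stratified five-fold
cross-validation: each iteration redraws fold assignments (stratified on
the event indicator so every training split contains events), fits the
Cox model per training split (non-convergent fits retry with ridge
penalties 0.1 then 1.0), computes the concordance within each held-out
fold, and averages folds. The summary is the mean over iterations and
the confidence interval the empirical 2.5/97.5% quantiles of the
iteration values.

Two estimator properties matter when reading these numbers:

- Per-fold averaging, not pooling, keeps the null expectation at 0.5.
  Pooled out-of-fold linear predictors mix scores from models on
  different coefficient scales and pair samples against models that
  trained on them; measured on null data this biases the pooled
  concordance several points below 0.5.
- Even so, the CV concordance is only unbiased *marginally*. For a
  single fixed dataset the training and held-out chance associations
  are anti-correlated (their total is fixed), so a single null dataset
  typically reads ~0.44-0.48 at n=150 with 4 predictors. Calibration
  checks therefore average over fresh permutation replicates.

`km_logrank` fits the Cox model on the complete dataset, splits at the
median prognostic score, and returns the two-group log-rank p. Being
in-sample, this is anticonservative when several predictors are fitted;
with a single score column the split is a fixed partition and the null
p-value is uniform. `bootstrap_compare` draws paired resamples (redrawn
until they contain events), computes both feature sets' c-statistics on
the same resample, and returns the doubled smaller tail of the
difference distribution around zero (default 500 resamples).

## Synthetic data

`opncombat.simulate` draws an `N(0,1)` base matrix and plants, in SD
units: per-batch additive shifts and multiplicative scalings on a
configurable feature subset (level 0 is the reference; level *i* gets
shift `i*location_shift` and scale `scale_factor**i`), a latent binary
grouping adding a separation offset (bimodality), linear covariate
effects, and exponential proportional-hazards survival with independent
exponential censoring whose rate is solved numerically so the expected
censored fraction matches the request. A latent grouping can be
confounded with a binary batch variable at a requested phi correlation
(infeasible requests error) or with the outcome via a log-hazard
coefficient. Finally each feature is mapped to its own scale (log-uniform
over three decades) and offset, mimicking the heterogeneous ranges of
radiomic features; the rank-based tests and the PCA standardization must
be indifferent to this, and a test asserts they are.

Named fixtures pin the study conditions used throughout the tests:
`null` (two inert batch variables, 200 samples), `two_batch_shift`
(one variable, shift 0.8 SD, scale 1.5), `two_batch_vars` (two variables
with location+scale effects), `confounded_latent` (160 samples, 80
features, latent separation 3 SD on 80% of features, phi 0.4 with the
scanner variable, log-hazard 1.5 on survival, 30% censoring), and
`lung3_like` (84 samples, three batch variables with fixed imbalanced
level counts 34/50, 49/35, 37/47, a latent grouping, clinical covariates
and ~45% censoring — patterned on a two-scanner lung CT cohort).

What the generator does **not** emulate: realistic radiomic feature
covariance (features are independent given the planted structure),
non-Gaussian within-group feature distributions, missing data, and
batch effects on feature covariance. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not performance on
any particular real cohort.

## Problem sizes and defaults

Simulated studies use 84-200 samples and 50-1000 features, matching the
scale the methods target. The repeated-CV concordance defaults to 2000
iterations in the API; the bundled evaluations run 200 iterations, which
puts the Monte-Carlo error of the iteration mean well below the
quantile-CI width. Bootstrap comparisons default to 500 resamples.
EM restarts (10), EB tolerance (1e-4), AD p-value clipping
([0.001, 0.25]), alpha (0.05) and `min_group_fraction` (0.05) are fixed
as described above.

## Known limitations

- Nonparametric EB, reference-batch anchoring, and covariance-level
  harmonization are out of scope.
- The permutation search is exhaustive by design and refuses more than
  six batch variables.
- The grouping selector considers one feature at a time; a grouping
  expressed only jointly across features will be missed.
- The point-biserial test applies to binary variables; the ANOVA
  extension for multi-level variables is a pragmatic, flagged choice.
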