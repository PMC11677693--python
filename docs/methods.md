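# Methods

This note documents the models and numerical choices behind `metaboclock`,
what the synthetic generator does and does not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Clinical grouping

COPD is defined spirometrically by post-bronchodilator FEV1/FVC < 0.7.
GOLD grades follow the interval scheme on FEV1 percent predicted: GOLD 0
(FEV1 ≥ 80% and ratio ≥ 0.7), GOLD 1 (≥ 80%, ratio < 0.7), GOLD 2
(50–80%), GOLD 3 (30–50%), GOLD 4 (< 30%), PRISm (ratio ≥ 0.7 but
FEV1 < 80%). Boundaries sit on the healthier side (≥ 80 is GOLD 0/1;
ratio ≥ 0.7 is non-obstructed); the emphysema control cut is strict
(%LAA < 5) and the quit-years rule inclusive (≥ 5 y).

Analysis groups: *control_training* = never smokers, or former smokers who
quit ≥ 5 y ago, with GOLD 0 spirometry and %LAA < 5; *current_no_copd* =
current smokers passing the same normality test; *disease* = ever-smokers
failing it; never smokers failing it are *excluded* (a small group in the
source cohorts); former smokers who quit < 5 y ago but pass the normality
test fit no study group and are tagged *other*, excluded from training and
comparisons. Two former-smoker definitions coexist in the field (30-day
visit rule vs 5-year training rule); both are config fields of
`GroupDefinition`, and only the 5-year rule affects training eligibility.

## Harmonization

Stage order is fixed: **normalize → filter → impute → log2.**

- *Batch-median normalization* divides each metabolite by its observed
  within-batch median, so every (batch, metabolite) cell set has observed
  median exactly 1. The operation is idempotent and scale-invariant per
  batch; positivity of intensities guarantees a positive median.
- *Missingness classification* uses per-cohort missing fractions:
  `retained` (≤ 0.20 in both), `severe` (≥ 0.80 in either), `discrepant`
  (≤ 0.20 in one, between 0.20 and 0.80 in the other), `both_moderate`
  (the remainder). The published thresholds mix strict and non-strict
  phrasing; the resolution here is retained ≤ 0.20 and severe ≥ 0.80,
  with every class reported so nothing is silently dropped. Only
  `retained` metabolites proceed.
- *kNN imputation* treats **metabolites** as neighbors (the convention of
  the classic microarray imputation package the field uses), with distance
  = mean squared difference over co-observed samples, requiring ≥ 3
  co-observed samples for eligibility. A missing cell takes the mean of
  the first k = 10 eligible neighbors observed in that sample, walking
  neighbors in distance order (ties broken by metabolite id for
  determinism); with no eligible donor the metabolite's own observed
  median is used and a warning logged. Imputation runs on the normalized,
  pre-log scale; observed cells are never altered.
- *log2* requires a complete, strictly positive matrix and fails loudly
  otherwise.

## Score models

Elastic net in the glmnet parametrization (loss scaled by 1/(2n); penalty
λ(α‖β‖₁ + (1−α)‖β‖₂²/2)), coordinate descent via scikit-learn. Predictors
are standardized to unit variance on the training set (means/sds stored in
the model; coefficients recoverable on both scales), the outcome centered.

Model selection: a single 10-fold CV loop per α on the 0–1/0.05 grid, with
one seeded fold assignment shared across the grid so CV errors are
comparable. The λ path is geometric with 50 points from λ_max (the
smallest λ zeroing all coefficients) down to λ_max·10⁻³. CV standard error
is sd(fold MSEs)/√folds. Per α the 1-SE rule takes the largest λ with mean
MSE ≤ min + SE(min); across α the grid point with smallest CV MSE at its
1-SE λ wins ("best-performing model" operationalized as minimum mean CV
MSE, the only criterion consistent with a single CV loop). α = 0 is in the
grid but coordinate descent is unreliable at pure ridge, so the solver
floors the mixing parameter at 0.001 (glmnet's own documented near-ridge
practice); at that grid point selection simply means "all metabolites".

Prediction is `intercept + Σ β·(x−μ)/σ` over the selected metabolites; a
matrix lacking a selected metabolite is an error, never a zero-fill.

## Age acceleration

The trend of metabolomic on actual age is a cubic smoothing spline with
the roughness penalty on the second derivative and smoothing chosen by
generalized cross-validation (scipy's `make_smoothing_spline`). Duplicate
ages are collapsed to weighted means (the standard tie treatment).
Exactly linear data are reproduced to numerical precision (linear
functions are unpenalized) and residuals sum to ~0 (constants are
unpenalized). Outside the training age range the trend continues linearly
from the boundary slope, keeping extrapolation bounded.

`delta = age_metabolomic − age_spline`; classification uses **strict**
inequalities (> +7 accelerated, < −7 decelerated, boundary intermediate).
The 7-year default captured roughly the 10% tails in the motivating
cohorts and is config; a symmetric quantile rule (`tail_fraction=0.10`) is
offered as the alternative. Group comparisons use **Welch** t-tests (the
published analysis says only "t-test"; Welch is the robust default and all
shipped bound-type checks are robust to pooled-vs-Welch) and Pearson
chi-squared with Yates continuity correction on for 2×2 tables by default,
off otherwise; expected counts < 5 trigger a recorded warning.

## Associations, overlap, enrichment

Univariate models are per-metabolite simple OLS. The direction (phenotype
on metabolite) is a convention only: simple-regression slope sign and p
are symmetric in the two roles, so signed −log10 p outputs are unaffected.
p-values are floored at 1e-300 before logs. Concordance between age and
obstruction effects flips the FEV1/FVC slope sign by default, because a
*lower* ratio means *worse* obstruction; the orientation is explicit
config.

Set overlap uses the 2×2 in/out membership table over the retained-
metabolite universe with an uncorrected chi-squared test, reporting the
one-sided hypergeometric tail alongside — the two agree in order of
magnitude when expected counts are comfortable, and both are emitted
rather than forcing one.

Pathway overrepresentation is the one-sided hypergeometric (Fisher) tail
per pathway, with the sample odds ratio; the universe excludes unannotated
metabolites (they cannot contribute to any pathway count) and is
restricted to filter-passing metabolites. BH adjustment is applied within
each annotation level (sub-pathways and super-pathways separately, since
both levels are tested).

## Synthetic generator: what it emulates, and what a green test means

Per subject *i*, metabolite *m*:

    log2 x_im = b_m + s_m·(age_i + δ_i) + t_m·ratio_i + log2(f_{batch(i),m}) + ε_im

exponentiated to positive intensities. Signals are planted on the log2
scale so the pipeline's log2 step linearizes them exactly, and the latent
offset δ enters as additive effective age in *years*, so the ±7-year
classes are directly meaningful against truth.

Defaults (the stated world; chosen once, not tuned): 831 metabolites, 300
age-associated and 300 obstruction-associated with 150 shared; cohort
sizes 2000/1000 with 60% training-grade controls (1200/600 controls),
10% current smokers without COPD, 30% disease; ages uniform 45–80 y; age
slopes |s| ~ U(0.005, 0.04) log2/yr with random sign and obstruction
slopes |t| ~ U(1, 4) log2 per unit ratio, against noise sd 1.0 log2 units —
putting per-metabolite univariate correlations in the weak (≈ 0.05–0.35)
regime real metabolomic clocks aggregate over; 3 batches per cohort with
per-(batch, metabolite) factors U(0.5, 2); MCAR 2% plus detection-limit
censoring below the 5th percentile; 40 metabolites planted with
cohort-discrepant (~50%) and 20 with severe (~85%) missingness, placed on
non-informative metabolites so filter tests don't silently interact with
signal recovery; latent offset sd 5 y with correlation 0.5 to disease
severity; a 60-sub-pathway/8-super-pathway annotation with planted
metabolites concentrated in a quarter of the sub-pathways and ~15.5% of
metabolites unannotated. All draws flow from one seed through named
sub-streams (metabolites, subjects and missingness per cohort, pathways).

The generator does **not** emulate: platform chemistry or compound
misidentification, batch drift within batches, non-Gaussian noise,
metabolite–metabolite correlation beyond what shared covariates induce,
longitudinal sampling, or realistic comorbidity co-occurrence. A green
clock benchmark therefore establishes that the *pipeline* recovers a
planted linear signal of realistic per-metabolite strength across cohorts
with realistic missingness and batch structure — not that any particular
biological clock replicates.

## Numerical choices and degenerate inputs

- Matrix round trips are bit-exact: floats are written at `repr`
  precision and parsed with a correctly rounded strtod.
- Fold assignment is a seeded permutation cut into near-equal folds; a
  fold with < 2 samples is an error, as are constant outcomes, incomplete
  matrices at fit time, and metabolites with zero observed values at
  imputation time.
- Chi-squared tables with a zero margin, splines with < 4 distinct ages,
  evaluation vectors with zero variance, and p-values outside [0, 1] all
  raise instead of returning NaN.
- The 2×2 overlap statistic is 0 with p = 1 for degenerate (empty-margin)
  membership tables; empty input sets warn and return p = 1.

## Known limitations

- The elastic-net CV path standardizes per fold but anchors the λ path on
  the full training standardization; with 50 path points this is the
  standard glmnet-style approximation, not an exact per-fold path
  recomputation.
- The permutation cross-check of the chi-squared test brackets the
  asymptotic p between strict and non-strict discrete tails; on very
  sparse tables the asymptotic test remains anti-conservative, which is
  why low expected counts trigger warnings.
- Synthetic severity, spirometry and comorbidity marginals are plausible
  but not calibrated to any cohort's joint distribution; comparisons on
  synthetic tails demonstrate machinery, not effect sizes.
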