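# Methods

This note documents the statistical procedures implemented in
`shockmetab`, the design decisions taken where several defensible options
existed, and what the synthetic-data generator does and does not emulate.

## Study shape and data model

The pipeline targets a two-arm design (carbohydrate-prefed CPF vs fasted
FS) with four sampled compartments — liver, muscle, serum, urine — and six
timepoints: baseline (B), 45 min of shock (S45), 2/8/20 h of full
resuscitation (FR2, FR8, FR20) and 48 h post-shock (PR48).  Default panel
sizes are 51 (liver), 39 (muscle), 53 (serum) and 60 (urine) metabolites.
A `MetabolomicsDataset` holds one compartment's samples × metabolites
matrix with per-sample metadata; the on-disk form is a long/tidy
delimited table (one row per cell), which tolerates ragged panels across
compartments.  Missing measurements are empty cells and become NaN —
never zero, because urine abundances can be truly zero and the two must
not be conflated.

## Preprocessing

**Urine flow normalization.** Urine concentrations (mM) are multiplied by
urine output (cc/hr/kg) to correct for the concentration/dilution swings
across shock and resuscitation.  The unit factor is 1000, fixed by
dimensional analysis: mM = µmol/mL, so mM × cc/hr/kg = µmol/h/kg =
1000 nmol/h/kg.  Normalized abundances span several orders of magnitude,
so they are transformed as `log10(x + 0.1)`; the offset puts exact zeros
at −1 and an observed maximum near 5.9 × 10⁵ nmol/h/kg at ≈ 5.77.

**Order of operations.** Urine is normalized and log-transformed *before*
differencing and scaling; liver/muscle/serum enter differencing on the raw
concentration scale, because group means of those compartments are
conventionally reported on the concentration scale.  Whether urine
intervals are differenced on the log or the normalized-abundance scale is
configurable (`PreprocessConfig.urine_difference_scale`); the default is
the log scale, since the transform precedes all analysis.

**Interval differencing.** An interval contrast (S45−B, FR2−S45, FR8−FR2,
FR20−FR8) produces one row per animal observed at *both* endpoints;
animals missing either endpoint are listwise-excluded for that contrast
only, and the exclusion is logged.  Differencing per animal cancels
stable animal-level offsets, which is the point of the within-subject
design.

**Autoscaling.** Each analysis matrix is column-centered and scaled to
unit sample standard deviation (n−1 denominator).  Zero-variance columns
are dropped and reported rather than jittered: autoscaling is undefined
for them and PLS weights would be 0/0.

## Outlier screening

PCA is computed by SVD of the centered, autoscaled matrix; eigenvalues
are the sample variances of the scores.  The per-sample statistic on the
first two components is

    T²ᵢ = t²ᵢ₁/λ₁ + t²ᵢ₂/λ₂

with the small-sample F-based boundary
`2(n−1)/(n−2) · F_α(2, n−2)` at α = 0.95.  The F form rather than the χ²
asymptotic is used because contrast sizes here are ~30–40 samples.
Screening is single-pass (no iterative re-screening), and the retained
rows are re-autoscaled before PLS-DA; both choices are configurable.
Because autoscaling is a per-column affine map, re-autoscaling retained
raw rows and re-autoscaling retained scaled rows are identical.

Score signs follow the convention that each component's
largest-magnitude loading is positive, making outputs reproducible across
LAPACK builds.

## PLS-DA

Classes are coded as a single ±1 response (alphabetically first class is
+1); with two roughly balanced classes this is equivalent to two-column
indicator coding up to scaling, and the single-response NIPALS extraction
is exact in one pass per component:

    w_a = X_aᵀy / ‖X_aᵀy‖,  t_a = X_a w_a,  q_a = t_aᵀy / t_aᵀt_a,
    p_a = X_aᵀt_a / t_aᵀt_a,  X_{a+1} = X_a − t_a p_aᵀ

The response is centered internally and its mean restored at prediction,
so unbalanced training splits do not bias the decision threshold.  Scores
are mutually orthogonal and weights unit-norm (asserted in tests).
Predictions use b = W(PᵀW)⁻¹q on the training-scaled space; the
coefficient path for 1..A components is precomputed from one fit, which
is what makes the inner CV search cheap.  A continuous prediction of
exactly 0 is assigned to the first class — an explicit, documented
tie-break.  If the residual X becomes orthogonal to the response,
extraction stops early and the model simply carries fewer components.

R²Y (response variance explained by the training fit) is the headline fit
statistic; R²X is computed but secondary.

**VIP.** Wold's formulation:
`VIP_j = sqrt(p · Σ_a SSY_a w²_ja / Σ_a SSY_a)` with
`SSY_a = q_a² t_aᵀt_a`, so Σ_j VIP²_j equals the retained variable count.
Selection reports metabolites with VIP ≥ 1.0, truncated to the 10
largest; ties at the cap boundary are broken by metabolite name order so
reports are reproducible.

## Nested cross-model validation (2CV)

Each outer repeat draws a stratified 75/25 train/test split
(stratification avoids occasional single-class splits at these group
sizes).  On the training set, leave-10-out inner cross-validation —
implemented as consecutive folds of 10 from a seeded shuffle, since
enumerating all 10-subsets is combinatorially infeasible — scores the
held-out number of misclassifications (NMC) for every candidate component
count up to `a_max` (default min(n_train − 1, p, 10)); the count with the
smallest total inner NMC wins, ties resolved toward the smallest count
(parsimony).  The optimized model is refit on the full training set and
scored on the test set.  Over the outer repeats (default 100; reported
NMC ± sd implies repeated splits, so the count is a package choice) the
pipeline aggregates NMC mean ± sd, the pooled confusion matrix and its
accuracy; accuracy ≥ 80% sets the "potential model" gate.  The component
count re-chosen per outer repeat (rather than fixed once) is the default;
the final reported model is the full-data refit at the modal selected
count.

**Permutation significance.** The permuted statistic is the
cross-validated test NMC — the same quantity the models are optimized
on.  Each permutation relabels the samples uniformly at random and reruns
the identical outer CV with a reduced repeat count (default 10) for
tractability; the observed statistic uses the same reduced count, which
is what makes observed and null values exchangeable — without it the
permutation p is not calibrated.  The p-value uses the add-one rule,
`p = (1 + #{null ≤ observed}) / (1 + n_perm)`, so p never reaches 0 and
its minimum at 1000 iterations is ≈ 0.001.

The whole validation stack consumes seeds through a hierarchical
`SeedSequence`, so results are bit-reproducible for a fixed seed.

## Welch test

Scalar lab values (e.g. serum urea measured on a blood-gas analyzer
rather than by NMR) are compared with a two-sided Welch t-test
(unequal variances, Satterthwaite degrees of freedom), delegated to
`scipy.stats.ttest_ind(equal_var=False)`.

## Synthetic-data generator

The generator emulates the *shape* of the study so that every stage has
testable ground truth:

- **Concentrations** are log-normal: metabolite-level log10 means are
  drawn once per compartment (sd `mean_log_spread` = 1.25, which gives
  urine panels spanning ≥ 4 orders of magnitude), and each measurement
  adds a per-animal intercept (sd 0.15, shared across timepoints — it
  cancels in interval differences) plus block-equicorrelated noise
  (blocks of 5, ρ = 0.3, within-measurement sd 0.25 log10).
- **Urine** carries a per-timepoint flow profile that dips at S45
  (fluid-retention physiology during shock) with lognormal noise
  (CV 0.4), and each concentration is exactly zero with probability
  `zero_rate_urine` = 0.05.
- **Planted effects** are specified per (compartment, contrast,
  metabolite) as a standardized effect d on the *analysis scale* of that
  compartment: multiplicative (log10 shift) for urine, additive on the
  concentration scale for tissue/serum with the shift sized by the
  delta-method sd of a lognormal (ln10 · sd_log10 · mean).  Interval
  effects shift the later timepoint by d·√2 of the appropriate sd so the
  *change* differs by d standard deviations; the variance basis differs
  between timepoint and interval contrasts because the animal intercept
  cancels only in differences.  For urine the planted effect is exact on
  the log scale (up to the +0.1 offset at very small abundances); for
  tissue/serum it is exact to delta-method accuracy, so realized effects
  run slightly below nominal d for the heavier-tailed panels.
- **Dropout** is a per-phase Bernoulli process: a scalar per-group death
  probability is split 25%/75% of the hazard across the shock and
  resuscitation phases (deaths concentrate post-resuscitation), keeping
  the total death probability exactly the configured value; defaults are
  47% (CPF) and 28% (FS).  Shock-phase deaths truncate follow-up after
  S45, resuscitation-phase deaths after FR8.  One shared survival stream
  guarantees an animal dies in every compartment simultaneously.
- **Seeding** is hierarchical: per-compartment and per-animal
  `SeedSequence` substreams mean that adding or removing a compartment
  never perturbs another compartment's draws.

What the generator does **not** emulate: realistic metabolite covariance
learned from data (block equicorrelation is a stylized stand-in),
hemodynamics or lactate physiology, measurement batch effects, and
compartment-specific missingness mechanisms.  Passing tests therefore
demonstrate the pipeline's statistical behavior under a controlled,
study-shaped null/alternative — not biological fidelity of any particular
metabolite.

## Numerical conventions and degenerate inputs

- Zero-variance columns: dropped at autoscaling, reported by name.
- PCA rank: the screen refuses matrices whose second eigenvalue is below
  1e-10 (absolute, or 1e-12 relative to the first).
- NIPALS early stop: component extraction halts when ‖Xᵀy‖ falls below
  1e-12 of ‖y‖.
- Inner folds with a single-class training remainder are skipped with a
  warning; if all folds are skipped the selection defaults to one
  component.
- All file output uses 12 significant digits, making write→read→write
  byte-stable; reports round to 6 significant digits.

## Problem sizes in the test suite

Property and calibration tests run at reduced scale chosen as the
package's own test design: permutation-p calibration uses 200 null
datasets of 28 samples × 8 variables with 99 permutations and 10 outer
repeats per statistic; planted-effect recovery uses 20 seeded studies of
16 animals/group × 40 metabolites (d = 2 on 5 metabolites).  These sizes
keep the full suite near three minutes on one CPU while leaving the
Monte-Carlo error bands meaningful; all thresholds (type-I error within
3 Monte-Carlo se of 5%, Kolmogorov–Smirnov uniformity p > 0.01, ≥ 80%
recovery and rejection rates) are stated in the tests themselves.

## Known limitations

- Only two-class discrimination (the design's two arms); no multi-class,
  OPLS-DA, kernel or sparse PLS variants.
- Q² is deliberately not computed; NMC is the optimization and reporting
  criterion throughout.
- No imputation: analysis rows with missing values are excluded per
  contrast.
- The Hotelling screen assumes approximate multivariate normality of the
  score plane; heavy-tailed contamination inflates the eigenvalues and
  makes the screen conservative.
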