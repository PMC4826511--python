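# Methods

## The model family

All five contrasts are generalized linear models of a later outcome Y on
linear combinations of a child's serial weight-for-length z-scores
z₀, z₁.₅, z₃, z₆, z₁₂, z₂₄ (subscripts are target ages in months). With
Δ_k = z_{t_k} − z_{t_{k−1}}, the designs are:

* **(a) conditional growth**, period k: {z₀, …, z_{t_k}} — the coefficient
  on z_{t_k} is growth in the latest interval conditional on all earlier
  sizes; a sequence of models is fitted, one ending at each age.
* **(b) being bigger**, period k: {z₀, Δ₁, …, Δ_k} — the z₀ coefficient is
  the effect of being one z-score bigger from birth to t_k, holding all
  intermediate changes fixed ("At birth" is the z₀-only model).
* **(c) becoming bigger and staying bigger**: {z₀, Δ₁, …, Δ₅} fitted once;
  each Δ coefficient is a gain in that interval that persists to 24 months.
* **(d) growing faster v being bigger**, period k: {Δ₁, …, Δ_k, z_{t_k}} —
  the coefficient on the last Δ compares conditional growth against being
  bigger among children of the same size at t_k.
* **(e) becoming bigger v being bigger**: {Δ₁, …, Δ₅, z₂₄} fitted once.

An intercept is always included, and adjustment covariates (sex,
gestational age, both entered linearly) are appended to every model so the
cross-model identities remain exact. The default link is logit with Wald
95% intervals and two-sided Wald p-values, exponentiated for OR reporting;
an identity link supports continuous outcomes. No multiplicity adjustment
is applied — the tables are descriptive, one block per contrast.

Because every design ending at the same age spans the same column space,
the following hold exactly at the MLE and are verified numerically by
`growthcontrasts.validation` (and by the `validate` CLI subcommand):
η_k = β_k − γ₀(t_k), θ_k = δ_k − γ₀(24 m), the final-period coefficients of
(a)/(c) and (d)/(e) coincide, all full-span models share fitted
probabilities and log-likelihood, and conditional-growth residuals are
pairwise uncorrelated in-sample.

**Tolerances.** Identities limited only by IRLS convergence are checked at
1e−6; literally-same-model equalities at 1e−8; closed-form OLS
orthogonality at 1e−10. GLMs run up to 200 IRLS iterations with a deviance
tolerance of 1e−10, leaving observed deviations near machine precision
(~1e−13 in practice). Rank deficiency is detected before fitting and
reported with the names of the collinear columns; perfect separation and
non-convergence are surfaced as flags on the fit, never silently.

## Two-step residual fits and standardisation

Each contrast coefficient has a two-step counterpart: OLS-regress the
period's growth construct on its conditioning set (response and regressors
as tabulated in `residuals.first_step_terms`), save the residuals ε_i, then
fit the outcome on ε_i plus covariates. Standardisation divides ε_i by
SD(ε_i) (n−1 denominator throughout the package), so the second-step
coefficient is per 1 SD of period-specific re-ordering. Exactly rescaling
a single regressor leaves the Wald z and p unchanged, and the standardised
coefficient equals the unstandardised one times SD(ε) — both asserted to
1e−8/1e−10. With the identity link and no covariates the two-step estimate
reproduces the one-step coefficient exactly (a Frisch–Waugh–Lovell
projection argument: ε is orthogonal to the conditioning span); with the
logit link the two-step model spans a different column space, so it is the
procedure itself, not an algebraic identity, and the package treats its
output as the standardised report. After standardisation the
cross-parameterisation identities fail by design (different periods are
rescaled by different SDs); the test suite asserts both the failure and
that the one-step identities remain intact. First-step regressions do not
include sex or gestational age — covariates enter only the second
analytical model — though the transformer accepts any covariate-free or
covariate-augmented matrix the caller builds.

Residual SD summaries report all pairwise period ratios (a ratio of 1.6
means a 1-z gain in one period is 1.6× the population re-ordering of the
other), and a density summary with a fixed 0.25-z bin width supports the
usual overlay histogram of period scores.

## Data preparation

* **LMS z-scoring**: z = ((x/M)^L − 1)/(L·S), with the L→0 limit
  ln(x/M)/S engaged below |L| = 1e−8; strictly increasing in x and
  invertible (round-trip asserted to 1e−10). L/M/S values are interpolated
  linearly in age within (sex, measure); ages outside the reference range
  are an error, not an extrapolation.
* **Reference tables**: externally fitted L/M/S tables are first-class
  input (CSV: sex, age, measure, L, M, S). The built-in
  `fit_empirical_reference` is a deliberately simple bin-wise stand-in
  (L = 1, M = cell mean, S = cell CV, ≥20 observations per cell, rows at
  bin midpoints) for smoothed LMS curve estimation, which is out of scope.
* **Interpolation to targets**: each target age owns a half-open assignment
  window reaching halfway to its neighbours (unbounded at the schedule
  ends). In-window observations that bracket the target are linearly
  interpolated on the z scale; otherwise the nearest in-window observation
  is carried; no in-window observation leaves the target missing.
  Bracketing is window-limited on purpose: a child with no measurement
  anywhere near 12 months should be missing there, not silently
  interpolated across half of infancy.
* **Conditional weight-for-length**: z(wt|len) = (z_wt − r_t z_len)/√(1 −
  r_t²) with r_t the Pearson correlation of the weight and length z
  columns at target t, computed on the complete-case analysis sample by
  default or supplied externally. |r_t| ≥ 1 (collinear input) is rejected.
  Under bivariate-normal margins the output has unit variance, asserted by
  simulation.
* **Outcome**: either attached per child or derived from a later
  measurement as BMI = kg/m² compared to an age- and sex-interpolated
  cutoff table (IOTF-style, user-supplied); BMI equal to the cutoff counts
  as overweight (inclusive boundary, configurable by editing the table).
* **Complete cases**: children missing any target z, the outcome or a
  covariate are dropped, with per-reason counts logged and returned.

## The synthetic-cohort generator

The generator is the package's test bed and default data source. It
emulates: six serial z-scores per child from a zero-mean unit-variance
multivariate normal whose correlation decays with time separation,
corr(s,t) = exp(−rate·|log(s+1) − log(t+1)|) with rate 0.35 by default
(adjacent-visit correlations ≈ 0.73–0.85, farther pairs lower; both the
transform and the rate, or an explicit matrix, are user-overridable — the
defaults are plausible for infancy, not calibrated to any cohort); sex ~
Bernoulli(0.5); gestational age ~ Normal(40, 1.8) weeks resampled into
[30, 44]; and a Bernoulli outcome from a logistic model on the full-span
design of a chosen contrast, with the default intercept (−2.0) giving
roughly 12% prevalence before covariate effects. Gestational age enters
the generating linear predictor centred at 40 weeks so the intercept
anchors prevalence; the recovery experiment re-centres accordingly when
refitting uncentred.

Unbalanced raw records are built by inverting the preparation chain:
weight and length z columns are constructed around the conditional z
matrix so that their *sample* correlation equals the requested r (0.3 by
default) exactly — a Gram–Schmidt embedding, so the zero-jitter round trip
through `prepare` is exact to machine precision rather than merely O(n^−½)
— then visit ages are jittered (birth stays at 0; order-violating or
out-of-reference draws are resampled up to a retry cap, after which jitter
is clamped to half the smallest inter-visit gap with a warning) and
kilograms/centimetres recovered through the inverse LMS transform on a
synthetic reference of closed-form median curves.

What the generator does **not** emulate: missing visits (missingness is
injected by tests deleting rows), measurement error in weight/length,
age-varying weight–length correlation, skewed or heteroscedastic z
margins, secular trends, or within-period nonlinearity. Passing tests
therefore certify the algebra, the fitting stack and the pipeline
plumbing — not robustness to those real-data features.

## Problem sizes and experiment design

The identity suite runs on 50 cohorts of n = 900 (a realistic complete-case
analysis size); it completes in well under its 30 s budget on one CPU. The
parameter-recovery experiment uses 200 replicates at n = 2000 (95% CI
coverage required in [0.90, 0.99], i.e. within Monte-Carlo error of
nominal) plus a single n = 100 000 replicate checked within 3 analytic SEs.
The horse-racing property — conditional-growth coefficients rising toward
the outcome age when the outcome is generated from final size alone — is
asserted on the mean over 200 replicates of n = 600, since individual
replicates are noisy. Convergence checks on the generator use n = 100 000
with tolerance 0.02.

## Known limitations

* The bin-wise empirical reference is not a smoothed LMS fit; use external
  L/M/S tables for real analyses.
* Two-step logit fits are not algebraically identical to one-step
  coefficients (only the identity link is); standardised tables should be
  read as the procedure defines them.
* Complete-case restriction only; no imputation or likelihood-based
  missing-data handling.
* No interactions between periods, nonlinear terms, or growth-curve shape
  models (splines, tempo models); the contrasts are strictly linear in the
  z-scores.
* Wald intervals can misbehave near separation at small n or rare
  outcomes; the fit flags, but does not repair, such cases.
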