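# Methods

## Problem and model

An electronic nose (eNose) is an array of partially selective gas sensors —
here metal-oxide-semiconductor (MOS) resistors — producing one response per
sensor per sample (first-order data). Classical limit-of-detection theory is
zeroth-order: it needs a single signal. `enoselod` bridges the two by
reducing the array response to a univariate *surrogate signal* and applying
Currie-style hypothesis-testing limits to it.

### Detection decision

For blank signals with mean `x̄_b` and sample SD `s_b` (N−1 divisor), the
signal threshold is `y_LOD = x̄_b + k·s_b`. Through a calibration line with
slope `m` (the analytical sensitivity):

```
c_LOD = k·s/|m|                       (slope form)
c_LOD = k·s·(1 + h0)/|m|              (leverage-corrected)
h0    = 1/n + c̄²/Σ(c_i − c̄)²
```

with `s` either the blank SD or the line's residual SD (N−2 divisor). The
multiplier `k` fixes the false-positive (α) and false-negative (β)
probabilities: `k = z(1−α) + z(1−β) = 3.29` for α = β = 0.05 under
normality/homoscedasticity (commonly printed 3.3), and `k = 2·t(1−α, N_b−1)
= 3.72` for 9 blank replicates in the Student-t form. The degrees of freedom
are taken as `N_b − 1` because only the blank SD is t-distributed in this
usage. The LOQ uses the same formulas with `k = 10` (reciprocal of a 10%
acceptable relative SD), so LOQ = LOD·10/k always holds method-wise.

The leverage factor is implemented in two variants: the linear `(1 + h0)`
factor (default, `as_printed`) and `sqrt(1 + h0)`. The linear form follows
the formula as usually typeset in the applied literature; the square-root
form follows the uncertainty-propagation derivation it descends from. Both
are selectable and recorded in every estimate; we assert neither as the
"correct" one.

An **adjusted LOD**, `(x̄_b + k·s − b0)/m`, removes the implicit assumption
that the calibration intercept `b0` equals the blank mean. When sensors
respond more steeply at low concentrations, `b0 > x̄_b` and the unadjusted
slope-form LOD is biased upward; the adjusted value can, however, turn
negative and is then flagged invalid rather than clipped.

### Surrogate construction

* **PCA I** — PC1 scores of the standardized features are the surrogate;
  the LOD is the lowest *measured* level whose mean score exceeds the blank
  threshold. Only measured levels can be declared, so the result is an
  upper bound ("< c_min") when the lowest nonzero level already exceeds,
  and a not-detected sentinel when none does.
* **PCA II** — OLS of PC1 score on concentration; slope and residual SD (or
  blank-score SD) feed the leverage-corrected formula.
* **PCR / PLSR** — the predicted concentration is the surrogate; an OLS
  line of predicted on actual concentration (slope ≈ 1 for a good model)
  supplies `m`, and either its residual SD or the SD of the blanks'
  predictions supplies `s`. Models are fit on the entire dataset after
  component selection.

Surrogate LODs are invariant under affine transformations of the response
(Ortiz), which the test suite enforces to 1e−9; PC1 is sign-oriented to
correlate non-negatively with concentration so eigensolver conventions
cannot flip results.

Component counts are chosen by 5-fold cross-validation stratified by
concentration level, repeated 10 times. "The minimum number of components
giving low RMSE and high Q²" is not an algorithm, so it is operationalized
as the one-standard-error rule: per repeat, the smallest count whose mean
held-out RMSE lies within one SE (over folds) of the minimizer's; the final
choice is the median over repeats, floored when fractional (parsimony). Q²
is computed per held-out fold as 1 − SS_res/SS_tot and reported but does
not decide. Fold standardization uses training-fold statistics only.

Two literature alternatives are included for comparison: the
**coefficient-vector** method `ĉ_LOD = 3·s_blank(1×J)·b(J×1)` (dot product
of per-sensor blank SDs with the PLSR coefficient vector), whose known
failure mode — negative values when negative-coefficient sensors carry
large blank SDs — is detected and flagged; and the **MRE change-point**
heuristic (LOD = smallest level from which all consecutive changes of the
per-level mean relative error stay ≤ 1 percent point), flagged as
unsuitable when fewer than six nonzero levels are available, since the rule
presupposes many closely spaced concentrations.

## Feature extraction

Each measurement cycle has three phases: flush (B), baseline (A), sample
headspace (C). The per-sensor feature is

```
R = (C̄ − Ā) − mean over the day's blanks of (C̄_blank − Ā_blank)
```

where each bar is the mean of the last 10 points of the phase (plateau
average; shorter traces are averaged in full with a warning). Subtracting
the preceding baseline removes the slow baseline level; subtracting the
day's mean ethanol-reference response removes additive per-(day, sensor)
offsets *exactly* — the test suite asserts this cancellation. Features are
then z-scored per sensor with the sample SD (N−1, the package-wide
convention); statistics are stored for inverse transforms and held-out
rows. Normalization is computed over the full substance dataset (all days,
blanks included), matching the use of the entire dataset for final model
fits; per-day normalization is not offered because the day-offset component
is already removed by the reference correction.

## Synthetic studies and what they show

The generator emulates a dilution-series characterization: 5 levels
(0, 0.5, 1, 2, 4 ppm, blank included) × 3 days × 3 replicates = 45 samples
with 9 blanks, on a 62-sensor array. Per-sensor mean response is
Michaelis–Menten-like, `a_s·c/(1 + c/κ)` with κ = 10 ppm: quasi-linear at
low concentration with the steeper relative rise at low c that MOS sensors
show, and smooth (a piecewise-linear alternative was rejected as
non-smooth). Sensitivities `a_s` share one latent channel (loading CV
0.15); blank noise σ0 = 0.25 signal units puts PC1's explained variance of
the standardized features in the 92–98% band reported for well-behaved
arrays. Noise SD grows as `σ0 + λ·c` (λ = 0 by default: homoscedastic, the
regime the k-factors assume). Additive day drift (`day_drift_sd`) enters
per (day, sensor) so the reference correction cancels it exactly —
isolating what that correction can remove; its default is 0 at feature
level because corrected features carry no additive day component. An
optional second latent channel (`interferent_strength`) adds variance
uncorrelated with concentration, producing rank-2 studies for component-
selection tests. Trace-level simulation writes idealized flat plateaus
(stationary trailing windows) so that the full
segment → extract → correct pipeline reproduces the feature-level
generator to 1e−9 in the noiseless case.

The **oracle** gives the ground-truth detectability of the latent channel:
reading the array out along the sensitivity direction â, the projected
signal is `|a|·f(c)` and the projected blank noise SD is
`σ_eff = sqrt(Σa_s²σ_s²)/|a|`, so `f(c_LOD) = k·σ_eff/|a|`, inverted
analytically through the saturation curve and cross-checked by Monte-Carlo
simulation of the blank distribution (2·10⁴ replicates by default, with a
delta-method SE).

What passing tests on these studies do **not** show about real data: the
generator has no multiplicative drift, no humidity/temperature covariates,
no sensor poisoning, no memory effects between cycles, and Gaussian noise
throughout; real arrays violate all of these to some degree. Within the
model, one systematic effect is worth knowing: estimated LODs on the
default study run ~25% above the oracle in the median. Two mechanisms,
both properties of the estimators rather than implementation artifacts,
drive this: (i) the calibration line spans the full 0–4 ppm range, so
saturation attenuates the fitted slope relative to the true
low-concentration sensitivity (the standard advice that the calibration
range should not extend far above the LOD exists precisely for this), and
(ii) the reference correction injects day-blank-mean noise into every
sample. The recovery test therefore checks a median ratio band of
[0.75, 1.33] over 200 replicate studies rather than unbiasedness.

## Numerical choices and edge cases

* Sample SD (N−1) everywhere, including z-scoring.
* WLS weights default to reciprocal per-level replicate variances, pooled
  for levels with < 3 replicates; a ≥3-replicate level with zero variance
  raises with a pointer to pooled/explicit weights. The residual SD is the
  plain N−2 form on unweighted residuals in both OLS and WLS, keeping one
  RSD definition across the package.
* Negative calibration slopes (MOS features may fall with concentration)
  use |m| with a warning; the LOD is a magnitude.
* A deviation estimate that is zero within 1e−10 of the calibration's
  signal scale flags the estimate degenerate instead of reporting a
  spurious 0 ppm.
* All comparisons run on unrounded values; table rendering rounds to two
  significant digits, with "<" bounds and "*" invalidity markers.
* Fractional CV medians floor; stratified folds deal each level's shuffled
  members round-robin with a random starting fold, so levels with fewer
  members than folds degrade gracefully.
* Blanks are included in calibration fits, PCR/PLSR fits and the
  predicted-vs-actual line by default (they anchor the intercept); the
  blank-prediction SD is the `s_blank` deviation for regression methods.
* The MRE method excludes flagged blanks (relative error is undefined at
  c = 0) and raises on unflagged zero concentrations.

## Problem sizes used in tests

The acceptance-style checks use 500 replicate single-sensor calibrations
for estimator consistency, 200 replicate 45 × 62 studies for parameter
recovery, 20 study seeds × 10 CV repeats for component selection and
2·10⁴ Monte-Carlo blanks for the oracle — sizes chosen so the whole suite
runs in well under a minute per check while leaving Monte-Carlo standard
errors far smaller than the tolerances tested.

## Known limitations

* Only additive day effects are corrected; multiplicative drift
  (sensitivity change) passes through the reference correction and is not
  modeled by any estimator here.
* No variance-function modeling beyond WLS weighting; no critical-level /
  detection-capability split beyond the single-k scheme.
* The suitability verdict (LOD strictly below the odor-threshold lower
  bound and below the process-range upper bound) is a declared
  operationalization of an argued judgement, printed with every report so
  it can be audited or replaced.
* Reference bands are shipped constants in ppm for bottom-fermented beer;
  they are matrix-specific, and moving from a 5% ethanol model matrix to
  real beer can shift both the limits and the bands.
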