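# Methods

## Data model

The raw atom is one fly: isoline, sex, treatment, observed age in days, and a
death/censoring flag. Ages sit on the observation grid (multiples of the
3-day transfer interval): a death that happens inside an interval is only
*discovered* at the transfer closing it and is recorded there. Escaped or
accidentally killed flies are right-censored at the check where they were last
handled; flies alive at the end of observation are censored at the horizon.

## Life-table reduction

Records are reduced to death counts D and exposures E (fly-days) per
(isoline, sex, treatment, age bin), with 3-day bins by default (coarser
multiples are supported). A fly contributes the full bin width to every bin it
survives completely. For the *endpoint* bin the default is the actuarial
half-interval credit for deaths: because deaths are recorded at the closing
transfer, crediting the full interval makes the empirical rate
D/E = (1 − e^(−µw))/w, which saturates at 1/w (≈ 0.33/day for w = 3) no matter
how high the true hazard, flattening the fitted log-hazard curve at old ages.
The half credit gives D/E = (2/w)·tanh(µw/2), accurate to second order in µw.
Censored flies always receive their full residual exposure — they were seen
alive at their endpoint. `endpoint_exposure="full"` restores the naive
convention (under which total exposure equals total observed days exactly).

A hard limit of the 3-day design follows from the same algebra: hazards well
above ~1/w are unmeasurable, so analyses near the oldest observed ages (where
µ can exceed 0.3/day) are boundary-dominated. Validation windows in the
acceptance suite therefore run from the age of the 30th death in a stratum to
the age where its survivorship reaches 5%.

## Hazard model

Deaths per row are modelled as Poisson with mean µ·E (offset log E) and

log µ(x) = β₀ + β_sex + β_trt + β_sex:trt + f_{g}(x) + g_i(x)

- **Smooths** f_g: cubic B-splines, k = 10 basis functions per smooth, on
  uniform knots extended beyond the data range (the Eilers–Marx construction,
  so the 2nd-order difference penalty's null space is exactly
  {constant, linear-in-age} and the infinite-smoothing limit is a Gompertz
  straight line). One smooth per group as configured: shared, per sex, per
  treatment, or per sex × treatment (the full model). Each smooth carries a
  sum-to-zero constraint over its rows so the parametric terms stay
  identifiable.
- **Isoline effects** g_i: either a random intercept or, by default, *factor
  smooths* — one B-spline deviation curve per isoline, all sharing a single
  smoothing parameter, constrained to sum to zero across isolines at every
  basis coefficient (so the group smooth remains the average line, and the
  per-isoline predictions average exactly to the conditional curve). The
  factor-smooth penalty adds the basis null space to the difference penalty,
  making the block fully penalized: deviations shrink entirely to zero as
  their λ grows, i.e. they behave as random effects.
- **Fitting**: penalized IRLS (Newton with step halving) to a gradient norm
  below 1e−8 (relative to total deaths), with a machine-precision stationarity
  exit for the stiff huge-λ regime.
- **Smoothing selection**: conditional AIC = −2·loglik + 2·EDF, with EDF the
  trace of the influence matrix, minimized by coordinate descent over an
  11-point log-spaced λ grid (10⁻³…10⁷) plus one local refinement sweep. By
  default the group smooths share one λ (they are exchangeable blocks of the
  same type, and this halves selection cost); `share_smooth_lambda=False`
  gives every block its own. The isoline block always has its own λ. REML
  would be the natural alternative for the variance-component flavor of λ
  selection; it is not implemented — AIC keeps a single criterion for both λ
  and structure selection.
- **Model structure selection**: candidates differ in fixed terms, smooth
  structure and isoline effects; ranked by AIC, ties (< 1e−6) broken toward
  fewer EDF; non-converged candidates excluded with a warning.

Rows with E > 0 and D = 0 are retained (they carry information); zero-exposure
bins never reach the fitter. Predictions outside the fitted age range raise —
there is deliberately no extrapolation policy.

## Marginal vs conditional mortality

The *conditional* curve sets the isoline terms to zero in the prediction while
keeping them in the model. The *marginal* curve averages the per-isoline
hazards µ_i(x) with survivor weights w_i(x) ∝ S_i(x), where S_i integrates
µ_i by the trapezoid rule with a constant-hazard back-extension on
[0, first grid age]; at age 0 the weights are uniform. Because frail isolines
die out first, the marginal curve decelerates relative to the conditional one
— the classic frailty-heterogeneity signature. The curves carry a `flavor`
tag and differencing curves of different flavors is refused.

The generator side has an exact counterpart (`true_marginal_hazard`):
Gauss–Hermite quadrature over the log-normal frailty (self-checked against a
refined rule, error raised with the offending age on disagreement), a discrete
mixture over realized frailties, and a closed-form mean-1 gamma-frailty
variant for cross-checks.

## Bootstrap difference bands

Differences Δ(x) = log µ_A(x) − log µ_B(x) get pointwise percentile bands:
individuals are resampled with replacement within each
isoline × sex × treatment cell (design-preserving; a cluster bootstrap over
isolines is available but 14 clusters is too few for stable quantiles), the
life table is rebuilt and the model refit with λ frozen at the original values
(re-selection per replicate available behind a flag). Default n_boot = 1000;
a band requires at least 200 successful refits; more than 10% refit failures
aborts. The grid is the life-table bin midpoints observable in both strata.
Significant windows are maximal runs of grid ages where the band excludes
zero, signed by the point estimate.

The bands are *pointwise*, not familywise. Measured consequence at the study
design: pointwise exclusion under a true null is calibrated in mid-life
(~4–5%) but rises to ~13–17% at ages below ~20 days, where each arm has only
~40 deaths and a chance imbalance is linearly extrapolated to the curve
boundary; scanning all grid ages for *any* window then flags some spurious
window in roughly a third to a half of null replicates. Interpret isolated
early or boundary windows with corresponding caution; mid-life windows are
trustworthy at close to nominal level.

## Synthetic cohorts

The generator emulates the study design: 14 isolines × 2 sexes ×
2 treatments × 90 flies, 3-day checks, per-check censoring probability 0.002
(the observed censoring rate is not documented; this placeholder is exposed in
the config), horizon 150 days. The individual hazard is

µ_{i,s,t}(x) = exp( log a_{s,t} + b·x + z_i + h_s·1[treated]·e^(−x/10) )

with z_i ~ N(0, σ²) per isoline. Defaults: b = 0.08/day and σ = 0.3 (the
values the validation criteria simulate), hump h = 0.7 at age 0 decaying over
10 days in the treated arm only, and baselines a = 1.5e−3/day (females) and
2.8e−3/day (males). The baselines were chosen to make the emulated cohort
show the qualitative features the analysis is built to detect: medians near
45 d (females) and 36 d (males), a male excess of ~0.6 on the log-hazard
scale, and an early treated-vs-control survivorship gap of a few percentage
points — large enough to be visible on a KM plot, as in the motivating
experiments. Latent death times invert the cumulative hazard on a 0.05-day
grid; deaths are then discretized upward to the next check. A design whose
horizon truncates more than half the latent deaths is rejected as
implausible.

What the generator does *not* emulate: within-isoline individual frailty,
vial-level effects (the design pools vials), seasonal/handling drift, and any
non-Gompertz baseline shape. Passing tests therefore demonstrate correctness
of the machinery under the stated stochastic model, not robustness to those
real-data features.

## Rank tests

Gehan scores are computed per stratum with the standard right-censoring
convention (a death at t is outlived by censorings at or after t; ties among
deaths score zero) and summed over the first group. The null is the
permutation of group labels within strata: exact enumeration when the total
number of arrangements is ≤ 10⁶ (per-stratum subset sums convolved), seeded
Monte-Carlo with p = (1+k)/(1+m) otherwise, or a normal approximation using
the exact permutation variance (tie-corrected through the realized scores).
Two-sided p throughout. The permutation null is the authoritative method;
the asymptotic path is labelled approximate.

## Problem sizes used in validation

All heavy checks run at the full study design (5 040 flies). Replicate
counts, sized for a single CPU: Gompertz slope recovery 50 cohorts; rank-test
null calibration 500 simulations (999 permutations each); hump-detection
power 25 cohorts and null-window rate 25 cohorts (n_boot = 200 per cohort);
AIC structure selection 25 cohorts; marginal-oracle agreement one cohort of
~20 000 flies. The acceptance script reports the same quantities at reduced
replicate counts (10 slope cohorts, 8 + 8 band cohorts, n_boot = 300 for the
main cohort's bands).

## Known limitations

- The early-age false-positive leak of pointwise percentile bands described
  above; no familywise correction is applied by design.
- Hazards above ~1/check-interval are unidentifiable from interval-censored
  counts; curves near the last observed ages are boundary-dominated.
- AIC-based λ selection is lighter-tailed than REML and can undersmooth in
  small strata.
- The Gehan-score tie convention is the documented mid-rank one; other ties
  treatments exist, and with heavy grid ties small-sample p-values can differ
  between conventions (the permutation null makes any fixed convention valid).
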