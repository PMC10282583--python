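# flymort

Age-specific mortality analysis for fly cohort experiments: from individual
death/censoring records to log-mortality difference curves with bootstrap
confidence bands.

## The problem

A common *Drosophila* demography design follows inbred **isolines** (here 14),
each contributing single-sex groups of ~90 flies to a control and a treated
arm. Flies are transferred to fresh vials every 3 days; at each transfer dead
flies are counted and escapees are recorded as right-censored. The scientific
questions are age-specific: *when* does a developmental treatment raise
mortality, and how do the sexes differ across the lifespan — questions that
cumulative survivorship curves blur but mortality-rate curves answer.

`flymort` implements that analysis end to end:

- **Kaplan–Meier** product-limit survivorship per group, and the **stratified
  Gehan–Breslow** (generalized Wilcoxon) test with an exact / Monte-Carlo
  permutation null — sensitive to early survival differences and robust to
  non-proportional hazards.
- A **life-table reduction** to per-bin death counts D and fly-day exposures
  E, the sufficient statistics of the hazard model (`log E` enters as offset).
- A **penalized-spline Poisson model** of log mortality,

  `log mu(x) = beta_sex + beta_trt + beta_sex:trt + f_{sex,trt}(x) + g_isoline(x)`

  with cubic P-spline smooths `f` per sex × treatment group and per-isoline
  **factor smooths** `g` (random smooth deviations sharing one smoothing
  parameter, summing to zero across isolines). Smoothing parameters and model
  structure are chosen by **AIC**.
- **Marginal vs conditional mortality**: the conditional curve zeroes the
  isoline effects; the marginal curve averages per-isoline hazards weighted by
  each isoline's surviving fraction, capturing the deceleration caused by
  heterogeneity in frailty (frail lines die out first).
- **Difference bands**: pointwise 95% bootstrap percentile bands for
  `log mu_A(x) − log mu_B(x)` from design-preserving resampling of
  individuals, with the maximal age windows where the band excludes zero.
- A **synthetic-cohort generator** (Gompertz baseline `log mu = log a + b x`,
  log-normal isoline frailty, treatment-specific early-adult excess) so every
  stage is testable against known ground truth, plus the exact quadrature
  oracle for the marginal hazard.

## Worked example

```python
import flymort as fm

# a synthetic study: 14 isolines x 2 sexes x 2 treatments x 90 flies
cohort = fm.simulate_cohort(fm.CohortDesign(seed=1), fm.GompertzFrailtyParams())

test = fm.gehan_breslow_stratified(cohort, compare="treatment", strata="sex")
print(f"treatment | sex strata: z = {test.statistic:.2f}, p = {test.p_value:.4f}")

lt = fm.build_lifetable(cohort)                 # 3-day bins, D and E per stratum
fit = fm.fit_hazard_model(lt, "full")           # AIC-selected smoothing
print(f"AIC = {fit.aic:.1f}, EDF = {fit.edf:.1f}")

boot = fm.bootstrap_refits(cohort, fit, n_boot=1000, seed=1)
for sex in ("female", "male"):
    band = fm.difference_band(fit, boot, (sex, "control"), (sex, "rapamycin"),
                              flavor="marginal")
    print(f"{sex}: significant windows:", band.significant_windows)
```

prints

```
treatment | sex strata: z = 3.26, p = 0.0011
AIC = 4851.4, EDF = 34.4
female: significant windows: ((1.5, 19.5, -1),)
male: significant windows: ((1.5, 13.5, -1),)
```

The negative windows say control mortality sits significantly *below* treated
mortality over ages 1.5–19.5 days (females) and 1.5–13.5 days (males) — the
treated arm's early-adult excess — while the marginal curves are
indistinguishable for the rest of life.

The command line mirrors the library: `flymort simulate | lifetable | kmtest |
fit | contrast | run`, with `flymort run --config cfg.yaml --seed 1` executing
the whole pipeline (KM + both stratified tests + model selection + the four
difference bands) and writing a manifest with input checksums and per-stage
timings.

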