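# Methods

`radonrisk` estimates lifetime fatal lung-cancer risk from residential
radon, resolved by geography and demographics and accounting for effect
modification by smoking. The engine is parameter-driven: three regression
models supply, for every demographic bin (county x age x sex x race x
poverty cell), an ever-smoking probability, a five-way house-type mix and a
per-type radon concentration, which a linear excess-risk formula converts
into a lifetime risk. This note records the models, the assumptions, the
numerical choices and what the synthetic data do and do not establish.

## The three regression models

**Radon concentration.** Indoor annual-average radon (pCi/L) is modelled as
lognormal: a linear model on log concentration with census region (Midwest
reference), county geological radon potential (USGS-style Low/Medium/High
summary, Low reference), annual heating-infiltration degree-days, average
diurnal temperature swing, and a five-category house type
(detached-with-basement reference), plus nested normal random intercepts
for state, primary sampling unit (county) and secondary sampling unit
(census tract) over the household-level residual. The packaged fixed
effects are the published point estimates; the level variances were not
published, so the packaged values (state 0.05, PSU 0.10, SSU 0.10,
residual 1.00 on the log scale) are explicit package assumptions used only
to drive the synthetic generator. Refitting uses REML through statsmodels
`MixedLM` with variance components for the two intermediate levels; a
noiseless input (zero residual variance) short-circuits to OLS, whose
estimates are exact in that degenerate case. Optimisation tries lbfgs,
bfgs, powell and Nelder-Mead in turn and raises `ConvergenceError` if none
converges.

**House type.** A single-level multinomial logistic model of five mutually
exclusive house types on poverty, sex, race, age group and census region
(South reference). House type is constant within a household, so household
clustering cannot be modelled; region is the only geographic covariate the
source survey supports. Association strengths are published as odds ratios
to two decimals; they are stored as printed and converted to log-odds by
natural log at load time, so recovered coefficients inherit that rounding.
Prediction is the softmax over the reference's zero linear predictor and
the four outcome-specific predictors; an explicit max-shift keeps the
exponentials stable. Fitting uses statsmodels `MNLogit` with lbfgs
(Newton steps wander on near-separated rare cells such as minors in
"other detached" units in the Northeast); a fitted coefficient exceeding
25 in absolute value is treated as separation and raised as an error.

**Ever-smoking.** A three-level logistic model of ever-smoking (current or
former — the stratum with the elevated radon unit risk) on sex, age group,
poverty, an income-not-reported indicator, race, race x male interactions,
state cigarette excise tax, previous (2003) state smoking prevalence, a
state indoor-smoking-restriction indicator and two CBSA indicators, with a
correlated state intercept/Black-race slope pair, a CBSA intercept and a
household intercept, all normal. Fitting delegates to lme4's `glmer`
(Laplace approximation, nAGQ = 1) through a bundled R script; glmmTMB
produces the same estimates but exits with a singular-convergence warning
at the scales we test, so lme4 is the backend.

The tax coefficient is implemented as printed (+0.08 per tax unit, OR
1.08) even though the source's own narrative describes a negative
association; the discrepancy is in the source and is not resolved here.
Tax units and the scale of the 2003 prevalence covariate (treated as
percentage points) are as-printed assumptions.

## Prediction conventions

- Radon predictions are exp(linear predictor) — geometric-scale
  predictions with no lognormal mean correction, because the downstream
  chain sums fixed effects and residuals only. `predict_concentration(...,
  mean_correction=True)` adds half the total random variance for users who
  want arithmetic means.
- Smoking predictions sum fixed effects plus state and CBSA residuals (and
  the state Black-slope residual for Black bins). The household random
  effect (variance 0.521) is never included and no marginalisation is
  applied, so predictions are conditional (median-household) probabilities.
  `marginal_prevalence` / `attenuation_diagnostic` quantify the gap by
  Gauss-Hermite quadrature (40 nodes; agrees with Monte Carlo to < 2e-3):
  at the reference logit -0.43 the population-average prevalence is ~0.41
  versus the conditional 0.394. The gap is surfaced, not silently
  corrected.
- Counties, states or CBSAs without estimated residuals keep zero
  residuals — predictions fall back to fixed effects, mirroring the
  treatment of areas absent from the source samples.
- The smoking model's islander race level is absent from the housing
  model; for house-type prediction it maps to the residual "other"
  category (configurable via `islander_as`).
- Covariates are applied raw, not centred (degree-days, diurnal swing, tax,
  prevalence), matching the printed-coefficient convention adopted here.

## The risk algorithm

Concentration converts to exposure at `0.004 WL/(pCi/L) x 51.6 WLM/WL-yr x
0.70 occupancy = 0.14448 WLM/yr per pCi/L` (the 40% progeny equilibrium
fraction is already embodied in the 0.004). Lifetime risk is `C x rate x D
x UR(sex, status)` with a fixed exposure duration D and unit risks per WLM
of 0.00106/0.000851 (male/female ever-smokers) and 0.000174/0.000161
(never-smokers). D is not published; the default 75 years is chosen
because it reproduces the published national benchmark — 0.73% lifetime
risk at 1.25 pCi/L with the general-population unit risk 0.00054 — to two
decimals, and it is configurable and logged.

Within a bin the expectation over the 5 x 2 house-type x smoking-status
combinations factorises exactly as
`(sum_h P_h C_h) x rate x D x [p UR_ever + (1-p) UR_never]`
under the assumption that smokers and non-smokers are distributed
identically across house types; an exhaustive-enumeration oracle in the
tests confirms the identity to 1e-12. Risks are clipped to [0, 1) with a
warning: the linear formula is only meaningful well below 1. Aggregation
is the bin-count-weighted mean of risk, concentration and smoking
prevalence at county, state or national level, plus an unweighted
across-county summary (mean/median/sd/range). This is a fixed-duration,
constant-concentration approximation; no life-table competing-risk
calculation and no uncertainty propagation are attempted.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the models assume —
four-level lognormal radon measurements, multinomial house types,
Bernoulli ever-smoking with correlated state intercept/slope, CBSA and
household effects, Poisson census-like bin counts (all 168 adult cells per
county) — with every outcome simulated exactly from the packaged
parameters, so generate -> fit -> predict closes on the generating model up
to sampling error. Covariate distributions are documented package defaults
chosen to span the design space: race mix 70/12/5/1/0.5/11.5%, age mix
13/18/19/19/13/10/8%, 13% below poverty, house-type mix 45/25/10/15/5%,
degree-days U[0, 9000], diurnal swing U[10, 35], tax U[0.2, 3], previous
prevalence U[15, 30] pp, household size fixed at 2.

They are *not* a miniature United States: real demographic margins,
spatial autocorrelation beyond the nesting, survey weights and migration
are out of scope. Because the printed intercepts were evidently calibrated
to centred covariates in the source fits, applying them to raw synthetic
covariates yields national averages (about 3 pCi/L, ever-smoking around
59%, risk around 2%) above the published US figures (1.3 pCi/L, 38.6%,
0.5%); the pipeline's *relative* geographic and demographic patterning,
not its absolute synthetic level, is what the tests establish. Passing
recovery tests show the estimators are consistent with their own
generating processes; they say nothing about fit to real measurements.

## Problem sizes and numerical tolerances

Parameter-recovery checks simulate at the source designs: 5,000 houses /
1,000 tracts / 125 counties / 44 states for radon (20 replicates), 50,000
persons for housing, and a reduced 40 states / 400 CBSAs / 30,000
two-person households for smoking (one replicate; a single Laplace fit of
60,000 binary observations with ~30,400 random effects). Recovery is
judged as pooled 2-SE coverage at the nominal 95% level, variances within
50% relative error. Known limitations found and documented by these runs:

- Wald/REML intervals for covariates that vary at the county or state
  level undercover slightly (z-score sd up to ~1.3 at 125 counties), so
  pooled radon coverage sits at ~94% rather than 95.5%.
- The Laplace approximation materially attenuates variance components for
  binary outcomes in two-person clusters: at the smoking acceptance scale
  the household variance is recovered ~46% low, the CBSA variance ~39%
  low, and the small state-level intercept variance (0.005) and Black-
  slope variance are effectively unidentifiable (fitted state correlation
  collapses to -1). Fixed effects attenuate correspondingly by a few
  percent. Adaptive quadrature is unavailable for multiple random-effect
  terms, so this is a recognised limit of the estimator class, not of the
  implementation.

Other numerical choices: concentrations are floored at 0.1 pCi/L before
the log transform (the published rescaling of negative instrument readings
is not reproducible from the source); probability simplexes are verified
to 1e-9; the factorisation identity to 1e-12; round-trip CSV I/O uses
round-trip float parsing so written results re-read bit-exactly; all
generators use `numpy.random.default_rng(seed)` and are byte-reproducible.
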