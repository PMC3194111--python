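# radonrisk

Screening-level cumulative risk assessment of residential radon in the
presence of smoking.

Radon is the leading cause of lung cancer in never-smokers, and its unit
risk per unit exposure is several-fold higher in ever-smokers, so the
geographic and demographic patterning of lung-cancer risk from radon
depends jointly on where radon concentrates and where smokers live.
`radonrisk` links three regression models to evaluate that joint pattern
for demographic *bins* — county x age x sex x race x poverty cells with
population counts, the finest cross-tabulation available from census
data — and aggregates population-weighted risk to county, state and
national level. It is intended for exposure/risk modellers who want a
transparent, parameter-driven screening chain, with every stage refittable
on their own (or synthetic) data.

## The model chain

For a bin *b* in county *c*:

1. **Ever-smoking**: multilevel logistic model,
   `logit P(ever) = β'x_b + γ'z_c + u_state + u_cbsa (+ v_state·black)`,
   with a correlated state intercept/Black-race random slope, CBSA and
   household random effects (household effects are excluded from
   prediction; the package reports the resulting marginal-vs-conditional
   attenuation).
2. **House type**: single-level multinomial logistic model over five types
   (detached with basement = reference; attached; crawl space; slab; other
   detached), `η_t = α_t + θ_t'x_b`, probabilities by softmax.
3. **Radon concentration**: log-linear model
   `log C = μ + region + geology + β₁·HDD + β₂·swing + housetype
   + u_state + u_county`, predicted per house type as `C_h = exp(lp)`.
4. **Risk**:
   `risk = (Σ_h P_h C_h) · 0.14448 WLM/yr/(pCi/L) · D ·
   [p·UR_ever + (1−p)·UR_never]`,
   with D = 75 years and sex-specific unit risks per WLM
   (male/female ever 0.00106/0.000851, never 0.000174/0.000161).

Published coefficients ship as editable CSV/TOML data files; each model
also has a statsmodels-style `Model(data).fit() -> Results` estimator
(`RadonConcentrationModel` via REML mixed model, `HouseTypeModel` via
multinomial MLE, `EverSmokingModel` via lme4's Laplace `glmer`, which
requires `Rscript` on PATH). A `synthetic_data`-style module
(`radonrisk.simulate`) generates geography, census-like bins and
survey-like person/house tables drawn exactly from the packaged models.
See `docs/methods.md` for assumptions and limitations.

## Worked example

```python
import radonrisk as rr

radon_p   = rr.load_coefficients("radon")
housing_p = rr.load_coefficients("housing")
smoking_p = rr.load_coefficients("smoking")
constants, unit_risks = rr.load_constants()

bin = rr.DemographicBin(county_id="17031", state_id="IL", age_group="45-54",
                        sex="male", race="white", poverty="above", count=4200)
ctx = rr.CountyContext(county_id="17031", state_id="IL", region="Midwest",
                       geo_potential="Medium",
                       heating_infiltration_degree_days=6500,
                       avg_diurnal_swing=18.0,
                       radon_state_residual=0.05,
                       smoking_state_residual=0.02,
                       state_cigarette_tax=0.98,
                       prev_state_prevalence_2003=22.5)
res = rr.bin_risk(bin, ctx, radon_p, housing_p, smoking_p,
                  constants, unit_risks)
```

prints (via the obvious f-strings):

```
P(ever-smoker)        = 0.680
house-type mix        = detached_with_basement: 0.576, attached: 0.367,
                        crawl_space: 0.035, slab: 0.017, other_detached: 0.004
E[concentration]      = 3.93 pCi/L
lifetime risk         = 0.0331  (3.31%)
```

Midwestern above-poverty white men in a medium-geology, cold county have
high odds of basement homes (higher radon) *and* high smoking odds, so
their lifetime risk, 3.3%, sits well above the ~0.7% national benchmark —
the compounding the chain is built to expose. Note the tobacco covariates
are applied on their raw scales, which pushes absolute levels above the
published reference profile (see `docs/methods.md`).

A command-line interface mirrors the library:

```sh
radonrisk simulate --what geography --seed 1 --out contexts.csv
radonrisk simulate --what bins --contexts contexts.csv --seed 2 --out bins.csv
radonrisk risk --bins bins.csv --contexts contexts.csv --out results.csv --level state
radonrisk fit-radon --in nrrs_like.csv --out radon_coefs_fit.csv
```

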