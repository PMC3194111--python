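"""Synthetic-data generators with the statistical structure the models assume.

The restricted surveys behind the published models cannot be redistributed,
so every input table is emulated: a synthetic geography of states, counties
and metro areas (CBSAs) with model residuals drawn from the published
variance components; census-like demographic bin counts; and person/house
level survey tables simulated exactly from the three regression models, so
that fitting recovers the generating parameters up to sampling error.

Covariate distributions (race/age/poverty mixes, meteorology and tax
ranges) are package-documented defaults chosen to span the design space of
US counties; they are not estimates of real US margins.  All generators are
deterministic given ``seed`` and emit tables directly consumable by the
fitting and prediction APIs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import vocab
from .exceptions import ValidationError
from .parameters import (HousingModelParams, RadonModelParams,
                         SmokingModelParams)
from .types import DemographicBin

# documented default covariate mixes for synthetic populations
RACE_MIX = {"white": 0.70, "black": 0.12, "asian": 0.05, "native": 0.01,
            "islander": 0.005, "other": 0.115}
AGE_MIX = {"18-24": 0.13, "25-34": 0.18, "35-44": 0.19, "45-54": 0.19,
           "55-64": 0.13, "65-74": 0.10, "75+": 0.08}
POVERTY_BELOW = 0.13
HOUSE_TYPE_MIX = {"detached_with_basement": 0.45, "attached": 0.25,
                  "crawl_space": 0.10, "slab": 0.15, "other_detached": 0.05}
GEO_MIX = {"Low": 0.4, "Medium": 0.4, "High": 0.2}
HDD_RANGE = (0.0, 9000.0)       # degree-days/year
SWING_RANGE = (10.0, 35.0)      # degrees
TAX_RANGE = (0.2, 3.0)          # state cigarette excise tax, table scale
PREV_RANGE = (15.0, 30.0)       # previous state smoking prevalence, % points


def _regions_for_states(n_states: int) -> np.ndarray:
    return np.array([vocab.REGIONS[i % 4] for i in range(n_states)])


def generate_geography(n_states: int = 44, n_counties: int = 125,
                       n_cbsas: int = 60, seed: int = 0,
                       radon_params: RadonModelParams | None = None,
                       smoking_params: SmokingModelParams | None = None
                       ) -> pd.DataFrame:
    """Synthetic county-context table (one row per county).

    Counties are distributed over states (each state gets at least one) and
    assigned to CBSAs within their state.  Residuals are drawn from normal
    distributions with the parameter bundles' variance components; with the
    packaged defaults this includes the correlated state black-race slope.
    """
    if min(n_states, n_counties, n_cbsas) <= 0:
        raise ValidationError("counts must be positive")
    if n_counties < n_states:
        raise ValidationError("need at least one county per state")
    if n_cbsas < n_states:
        raise ValidationError("need at least one CBSA per state")
    from .parameters import load_coefficients
    radon_params = radon_params or load_coefficients("radon")
    smoking_params = smoking_params or load_coefficients("smoking")
    rng = np.random.default_rng(seed)

    regions = _regions_for_states(n_states)
    county_state = np.concatenate([
        np.arange(n_states),
        rng.integers(0, n_states, n_counties - n_states)])
    cbsa_state = np.concatenate([
        np.arange(n_states),
        rng.integers(0, n_states, n_cbsas - n_states)])
    # each county joins a CBSA of its own state
    cbsa_by_state = {s: np.flatnonzero(cbsa_state == s) for s in range(n_states)}
    county_cbsa = np.array([rng.choice(cbsa_by_state[s]) for s in county_state])

    vc = radon_params.variance_components
    radon_state_re = rng.normal(0, np.sqrt(vc.get("state", 0.0)), n_states)
    radon_county_re = rng.normal(0, np.sqrt(vc.get("psu", 0.0)), n_counties)
    cov = np.array([
        [smoking_params.var_state, smoking_params.cov_state_blackslope],
        [smoking_params.cov_state_blackslope,
         smoking_params.var_state_black_slope]])
    smoke_state_re = rng.multivariate_normal([0.0, 0.0], cov, n_states)
    smoke_cbsa_re = rng.normal(0, np.sqrt(smoking_params.var_cbsa), n_cbsas)

    tax = rng.uniform(*TAX_RANGE, n_states)
    prev = rng.uniform(*PREV_RANGE, n_states)
    restrict = rng.integers(0, 2, n_states)
    cbsa_pov = rng.integers(0, 2, n_cbsas)
    cbsa_nonmetro = (rng.random(n_cbsas) < 0.3).astype(int)

    rows = []
    for c in range(n_counties):
        s, cb = county_state[c], county_cbsa[c]
        rows.append({
            "county_id": f"C{c:04d}", "state_id": f"S{s:02d}",
            "cbsa_id": f"B{cb:03d}", "region": regions[s],
            "geo_potential": rng.choice(list(GEO_MIX), p=list(GEO_MIX.values())),
            "heating_infiltration_degree_days": rng.uniform(*HDD_RANGE),
            "avg_diurnal_swing": rng.uniform(*SWING_RANGE),
            "radon_state_residual": radon_state_re[s],
            "radon_county_residual": radon_county_re[c],
            "smoking_state_residual": smoke_state_re[s, 0],
            "smoking_state_black_slope": smoke_state_re[s, 1],
            "smoking_cbsa_residual": smoke_cbsa_re[cb],
            "state_cigarette_tax": tax[s],
            "prev_state_prevalence_2003": prev[s],
            "indoor_restriction_flag": int(restrict[s]),
            "cbsa_poverty_above_median": int(cbsa_pov[cb]),
            "cbsa_nonmetropolitan": int(cbsa_nonmetro[cb]),
        })
    return pd.DataFrame(rows)


def generate_census_bins(contexts: pd.DataFrame, mean_pop: float = 10000.0,
                         seed: int = 0) -> pd.DataFrame:
    """Census-like adult bin counts for every county in ``contexts``.

    Every county emits all 7 x 2 x 6 x 2 = 168 adult cells; counts are
    Poisson with mean ``mean_pop`` x cell weight, the weights being the
    product of the documented marginal age/sex/race/poverty mixes.
    """
    if mean_pop <= 0:
        raise ValidationError("mean_pop must be positive")
    rng = np.random.default_rng(seed)
    cells = [(a, s, r, p)
             for a in vocab.AGE_GROUPS for s in vocab.SEXES
             for r in vocab.RACES for p in vocab.POVERTY]
    weights = np.array([
        AGE_MIX[a] * 0.5 * RACE_MIX[r]
        * (POVERTY_BELOW if p == "below" else 1 - POVERTY_BELOW)
        for a, s, r, p in cells])
    rows = []
    for rec in contexts.itertuples(index=False):
        counts = rng.poisson(mean_pop * weights)
        for (a, s, r, p), n in zip(cells, counts):
            rows.append({"county_id": rec.county_id, "state_id": rec.state_id,
                         "age_group": a, "sex": s, "race": r, "poverty": p,
                         "count": int(n)})
    return pd.DataFrame(rows)


def generate_nrrs_like(params: RadonModelParams | None = None,
                       n_houses: int = 5336, n_ssus: int = 977,
                       n_psus: int = 125, n_states: int = 44,
                       seed: int = 0) -> pd.DataFrame:
    """Simulated long-term radon measurement survey with 4-level nesting.

    House types, regions (state level), geological potential and
    meteorology (county/PSU level) are drawn from the documented mixes;
    log concentrations are the fixed-effect linear predictor plus normal
    state/PSU/SSU random intercepts and residual noise with the bundle's
    variance components.
    """
    from .parameters import load_coefficients
    params = params or load_coefficients("radon")
    if not (n_states <= n_psus <= n_ssus <= n_houses):
        raise ValidationError(
            "frame sizes must nest: n_states <= n_psus <= n_ssus <= n_houses")
    rng = np.random.default_rng(seed)
    psu_state = np.concatenate([np.arange(n_states),
                                rng.integers(0, n_states, n_psus - n_states)])
    ssu_psu = np.concatenate([np.arange(n_psus),
                              rng.integers(0, n_psus, n_ssus - n_psus)])
    house_ssu = np.concatenate([np.arange(n_ssus),
                                rng.integers(0, n_ssus, n_houses - n_ssus)])
    ssu = house_ssu
    psu = ssu_psu[ssu]
    state = psu_state[psu]

    regions = _regions_for_states(n_states)
    geo_psu = rng.choice(list(GEO_MIX), n_psus, p=list(GEO_MIX.values()))
    hdd_psu = rng.uniform(*HDD_RANGE, n_psus)
    swing_psu = rng.uniform(*SWING_RANGE, n_psus)
    ht = rng.choice(list(HOUSE_TYPE_MIX), n_houses,
                    p=list(HOUSE_TYPE_MIX.values()))

    vc = params.variance_components
    re_state = rng.normal(0, np.sqrt(vc.get("state", 0.0)), n_states)
    re_psu = rng.normal(0, np.sqrt(vc.get("psu", 0.0)), n_psus)
    re_ssu = rng.normal(0, np.sqrt(vc.get("ssu", 0.0)), n_ssus)
    eps = rng.normal(0, np.sqrt(vc.get("residual", 0.0)), n_houses)

    region_c = np.vectorize(
        lambda r: params.region_coefs[r])(regions[state])
    geo_c = np.vectorize(lambda g: params.geo_coefs[g])(geo_psu[psu])
    ht_c = np.vectorize(lambda h: params.housetype_coefs[h])(ht)
    log_c = (params.intercept + region_c + geo_c
             + params.hdd_coef * hdd_psu[psu]
             + params.diurnal_coef * swing_psu[psu]
             + ht_c + re_state[state] + re_psu[psu] + re_ssu[ssu] + eps)
    return pd.DataFrame({
        "house_id": [f"H{i:05d}" for i in range(n_houses)],
        "ssu_id": [f"T{i:04d}" for i in ssu],
        "psu_id": [f"P{i:04d}" for i in psu],
        "state_id": [f"S{i:02d}" for i in state],
        "house_type": ht, "region": regions[state],
        "geo_potential": geo_psu[psu], "hdd": hdd_psu[psu],
        "diurnal_swing": swing_psu[psu],
        "concentration": np.exp(log_c)})


def generate_ahs_like(params: HousingModelParams | None = None,
                      n: int = 50000, seed: int = 0) -> pd.DataFrame:
    """Simulated person-level housing survey drawn from the multinomial model."""
    from .housing import housing_linear_predictors
    from .parameters import load_coefficients
    params = params or load_coefficients("housing")
    if n <= 0:
        raise ValidationError("n must be positive")
    rng = np.random.default_rng(seed)
    # include minors at a documented 20% share: the source survey covers them
    age = rng.choice(vocab.HOUSING_AGE_GROUPS, n,
                     p=[0.20] + [0.80 * AGE_MIX[a] for a in vocab.AGE_GROUPS])
    sex = rng.choice(vocab.SEXES, n)
    race = rng.choice(vocab.HOUSING_RACES, n,
                      p=[0.705, 0.12, 0.05, 0.01, 0.115])
    poverty = np.where(rng.random(n) < POVERTY_BELOW, "below", "above")
    region = rng.choice(vocab.REGIONS, n)

    class _P:  # lightweight profile carrying the bin attributes
        __slots__ = ("age_group", "sex", "race", "poverty")

        def __init__(self, a, s, r, p):
            self.age_group, self.sex, self.race, self.poverty = a, s, r, p

    order = [vocab.HOUSE_TYPE_REF] + list(vocab.HOUSE_TYPE_OUTCOMES)
    # unique profiles -> probabilities, then vectorised draws
    df = pd.DataFrame({"age_group": age, "sex": sex, "race": race,
                       "poverty": poverty, "region": region})
    probs = np.empty((n, 5))
    for key, idx in df.groupby(list(df.columns)).groups.items():
        a, s, r, p, reg = key
        from .housing import housing_probabilities
        pr = housing_probabilities(_P(a, s, r, p), reg, params)
        probs[idx] = [pr[o] for o in order]
    u = rng.random(n)
    cum = probs.cumsum(axis=1)
    codes = (u[:, None] > cum).sum(axis=1)
    df["house_type"] = np.array(order)[codes]
    return df


def generate_cps_like(params: SmokingModelParams | None = None,
                      n_states: int = 40, n_cbsas: int = 400,
                      n_households: int = 30000, household_size: int = 2,
                      seed: int = 0) -> pd.DataFrame:
    """Simulated person-level tobacco-use survey from the multilevel model.

    Households nest in CBSAs nest in states; ever-smoking is Bernoulli at
    the inverse-logit of fixed effects plus state intercept, state
    black-race slope (drawn jointly with the stated covariance), CBSA and
    household random effects.
    """
    from .parameters import load_coefficients
    params = params or load_coefficients("smoking")
    if min(n_states, n_cbsas, n_households, household_size) <= 0:
        raise ValidationError("sizes must be positive")
    if n_cbsas < n_states or n_households < n_cbsas:
        raise ValidationError(
            "sizes must nest: n_states <= n_cbsas <= n_households")
    rng = np.random.default_rng(seed)
    cbsa_state = np.concatenate([np.arange(n_states),
                                 rng.integers(0, n_states, n_cbsas - n_states)])
    hh_cbsa = np.concatenate([np.arange(n_cbsas),
                              rng.integers(0, n_cbsas, n_households - n_cbsas)])
    n = n_households * household_size
    hh = np.repeat(np.arange(n_households), household_size)
    cbsa = hh_cbsa[hh]
    state = cbsa_state[cbsa]

    sex = rng.choice(vocab.SEXES, n)
    age = rng.choice(vocab.AGE_GROUPS, n, p=list(AGE_MIX.values()))
    race = rng.choice(vocab.RACES, n, p=list(RACE_MIX.values()))
    poverty = np.where(rng.random(n) < POVERTY_BELOW, "below", "above")
    inr = (rng.random(n) < 0.10).astype(int)
    tax = rng.uniform(*TAX_RANGE, n_states)
    prev = rng.uniform(*PREV_RANGE, n_states)
    restrict = rng.integers(0, 2, n_states)
    cbsa_pov = rng.integers(0, 2, n_cbsas)
    nonmetro = (rng.random(n_cbsas) < 0.3).astype(int)

    coefs = params.fixed_coefs
    male = (sex == "male").astype(float)
    age_c = np.vectorize(
        lambda a: 0.0 if a == vocab.AGE_REF else coefs[f"age:{a}"])(age)
    race_c = np.vectorize(
        lambda r: 0.0 if r == vocab.RACE_REF else coefs[f"race:{r}"])(race)
    race_m = np.vectorize(
        lambda r: 0.0 if r == vocab.RACE_REF else coefs[f"race_male:{r}"])(race)
    lp = (params.intercept + coefs["male"] * male + age_c
          + coefs["poverty:below"] * (poverty == "below")
          + coefs["income_not_reported"] * inr
          + race_c + race_m * male
          + coefs["state_tax"] * tax[state]
          + coefs["prev_state_prevalence"] * prev[state]
          + coefs["indoor_restrictions"] * restrict[state]
          + coefs["cbsa_poverty_above_median"] * cbsa_pov[cbsa]
          + coefs["cbsa_nonmetropolitan"] * nonmetro[cbsa])
    cov = np.array([[params.var_state, params.cov_state_blackslope],
                    [params.cov_state_blackslope,
                     params.var_state_black_slope]])
    re_s = (rng.multivariate_normal([0, 0], cov, n_states)
            if cov.any() else np.zeros((n_states, 2)))
    re_c = rng.normal(0, np.sqrt(params.var_cbsa), n_cbsas)
    re_h = rng.normal(0, np.sqrt(params.var_household), n_households)
    black = (race == "black").astype(float)
    eta = lp + re_s[state, 0] + black * re_s[state, 1] + re_c[cbsa] + re_h[hh]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame({
        "person_id": [f"I{i:06d}" for i in range(n)],
        "household_id": [f"H{i:06d}" for i in hh],
        "cbsa_id": [f"B{i:04d}" for i in cbsa],
        "state_id": [f"S{i:02d}" for i in state],
        "sex": sex, "age_group": age, "race": race, "poverty": poverty,
        "income_not_reported": inr, "state_tax": tax[state],
        "prev_state_prevalence": prev[state],
        "indoor_restrictions": restrict[state],
        "cbsa_poverty_above_median": cbsa_pov[cbsa],
        "cbsa_nonmetropolitan": nonmetro[cbsa],
        "ever_smoker": y})


def bins_from_frame_counts(bins_df: pd.DataFrame) -> list[DemographicBin]:
    """Convenience: frame -> validated DemographicBin records."""
    from .io import bins_from_frame
    return bins_from_frame(bins_df)
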