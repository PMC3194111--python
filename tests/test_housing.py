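"""House-type model: linear predictors, softmax probabilities, fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radonrisk import (HouseTypeModel, housing_linear_predictors,
                       housing_probabilities)
from radonrisk.exceptions import ValidationError
from radonrisk.parameters import HousingModelParams
from radonrisk.simulate import generate_ahs_like
from radonrisk.types import DemographicBin
from radonrisk.vocab import HOUSE_TYPE_OUTCOMES, HOUSE_TYPES


def _bin(**kw):
    base = dict(county_id="C1", state_id="S1", age_group="45-54",
                sex="female", race="white", poverty="above", count=1)
    base.update(kw)
    return DemographicBin(**base)


def test_reference_profile_etas_are_intercepts(housing_params, reference_bin):
    etas = housing_linear_predictors(reference_bin, "South", housing_params)
    assert etas == {"attached": 1.14, "crawl_space": -0.51, "slab": -0.30,
                    "other_detached": -2.80}


def test_below_poverty_adds_log_or(housing_params):
    etas = housing_linear_predictors(_bin(poverty="below"), "South",
                                     housing_params)
    assert etas["attached"] == pytest.approx(1.14 + math.log(4.40), 1e-12)


def test_midwest_adds_log_or(housing_params, reference_bin):
    etas = housing_linear_predictors(reference_bin, "Midwest", housing_params)
    assert etas["attached"] == pytest.approx(1.14 + math.log(0.21), 1e-12)


def test_reference_probabilities_hand_softmax(housing_params, reference_bin):
    probs = housing_probabilities(reference_bin, "South", housing_params)
    denom = 1 + math.exp(1.14) + math.exp(-0.51) + math.exp(-0.30) + \
        math.exp(-2.80)
    assert probs["detached_with_basement"] == pytest.approx(1 / denom, 1e-12)
    assert probs["detached_with_basement"] == pytest.approx(0.1809, abs=5e-5)
    assert probs["attached"] == pytest.approx(math.exp(1.14) / denom, 1e-12)
    assert probs["attached"] == pytest.approx(0.5655, abs=5e-5)


def test_all_zero_etas_give_uniform_fifths(housing_params, reference_bin):
    p = HousingModelParams(
        intercepts={o: 0.0 for o in HOUSE_TYPE_OUTCOMES},
        coefs={k: 0.0 for k in housing_params.coefs})
    probs = housing_probabilities(reference_bin, "South", p)
    assert all(v == pytest.approx(0.2, abs=1e-12) for v in probs.values())


def test_softmax_shift_invariance(housing_params, reference_bin):
    shifted = HousingModelParams(
        intercepts={o: v + 3.7 for o, v in housing_params.intercepts.items()},
        coefs=dict(housing_params.coefs))
    base = housing_probabilities(reference_bin, "South", housing_params)
    # shifting every non-reference eta by +c is NOT invariant; shifting all
    # five (incl. reference) is.  Emulate by subtracting c from the others.
    probs2 = housing_probabilities(reference_bin, "South", shifted)
    assert probs2["detached_with_basement"] < base["detached_with_basement"]
    np.testing.assert_allclose(sum(probs2.values()), 1.0, atol=1e-12)


@given(st.sampled_from(["white", "black", "asian", "native", "islander",
                        "other"]),
       st.sampled_from(["male", "female"]),
       st.sampled_from(["18-24", "25-34", "35-44", "45-54", "55-64",
                        "65-74", "75+"]),
       st.sampled_from(["below", "above"]),
       st.sampled_from(["Northeast", "Midwest", "South", "West"]))
@settings(max_examples=100, deadline=None)
def test_probabilities_valid_simplex(housing_params, race, sex, age, pov,
                                     region):
    probs = housing_probabilities(
        _bin(race=race, sex=sex, age_group=age, poverty=pov), region,
        housing_params)
    assert set(probs) == set(HOUSE_TYPES)
    assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(0 < v < 1 for v in probs.values())


def test_above_poverty_maximises_basement_probability(housing_params):
    """All printed poverty ORs exceed 1 toward non-basement outcomes."""
    for region in ("Northeast", "South", "West", "Midwest"):
        above = housing_probabilities(_bin(poverty="above"), region,
                                      housing_params)
        below = housing_probabilities(_bin(poverty="below"), region,
                                      housing_params)
        assert above["detached_with_basement"] > \
            below["detached_with_basement"]


def test_islander_maps_to_other_by_default(housing_params):
    isl = housing_probabilities(_bin(race="islander"), "South",
                                housing_params)
    oth = housing_probabilities(_bin(race="other"), "South", housing_params)
    assert isl == oth
    blk = housing_probabilities(_bin(race="islander"), "South",
                                housing_params, islander_as="black")
    assert blk != oth


def test_two_outcome_closed_form_oracle():
    """Binary sub-model MLE equals the log odds-ratio of the 2x2 table.

    Data restricted to two outcomes with one binary covariate: the
    multinomial MLE for that contrast has the closed contingency-table
    form ln((a/b)/(c/d)).
    """
    rng = np.random.default_rng(5)
    n = 4000
    pov = np.where(rng.random(n) < 0.4, "below", "above")
    p_att = np.where(pov == "below", 0.55, 0.30)
    ht = np.where(rng.random(n) < p_att, "attached", "detached_with_basement")
    # counts of the 2x2 table
    a = np.sum((pov == "below") & (ht == "attached"))
    b = np.sum((pov == "below") & (ht == "detached_with_basement"))
    c = np.sum((pov == "above") & (ht == "attached"))
    d = np.sum((pov == "above") & (ht == "detached_with_basement"))
    closed_form = math.log((a / b) / (c / d))

    import statsmodels.api as sm
    X = pd.DataFrame({"Intercept": 1.0, "pov": (pov == "below").astype(float)})
    fit = sm.MNLogit((ht == "attached").astype(int), X).fit(disp=False)
    assert fit.params.iloc[1, 0] == pytest.approx(closed_form, abs=1e-6)


def test_fit_smoke_recovers_strong_effects(housing_params):
    df = generate_ahs_like(housing_params, n=15000, seed=9)
    res = HouseTypeModel(df).fit()
    p = res.params
    # estimates land within 3 estimated SEs of the generating values
    assert abs(p.intercepts["attached"] - 1.14) < \
        3 * p.ses[("attached", "intercept", "")]
    for key, truth in ((("attached", "poverty", "below"), math.log(4.40)),
                       (("slab", "region", "Northeast"), math.log(0.03)),
                       (("attached", "region", "Midwest"), math.log(0.21))):
        assert abs(p.coefs[key] - truth) < 3 * p.ses[key]
    assert res.llf < 0


def test_fit_requires_all_outcomes(housing_params):
    df = generate_ahs_like(housing_params, n=2000, seed=2)
    df = df[df["house_type"] == "detached_with_basement"]
    with pytest.raises(ValidationError, match="absent"):
        HouseTypeModel(df)


def test_fit_rejects_unknown_race(housing_params):
    df = generate_ahs_like(housing_params, n=500, seed=2)
    df.loc[df.index[0], "race"] = "islander"
    with pytest.raises(ValidationError, match="islander"):
        HouseTypeModel(df)
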