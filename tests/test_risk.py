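"""Risk engine: exposure conversion, unit risks, bin chain, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radonrisk import (ExposureConstants, UnitRiskFactors, aggregate,
                       bin_risk, exposure_rate, lifetime_risk_for_status)
from radonrisk.exceptions import ValidationError
from radonrisk.types import BinRiskResult, CountyContext, DemographicBin
from radonrisk.vocab import HOUSE_TYPES


def _bin(**kw):
    base = dict(county_id="C1", state_id="S1", age_group="45-54",
                sex="female", race="white", poverty="above", count=100)
    base.update(kw)
    return DemographicBin(**base)


def _ctx(**kw):
    base = dict(county_id="C1", state_id="S1", region="Midwest",
                geo_potential="Low", heating_infiltration_degree_days=0.0,
                avg_diurnal_swing=0.0)
    base.update(kw)
    return CountyContext(**base)


def test_exposure_rate_printed_product(constants):
    assert exposure_rate(constants) == pytest.approx(0.004 * 51.6 * 0.70)
    assert round(exposure_rate(constants), 3) == 0.144


def test_exposure_rate_edge_values():
    full = ExposureConstants(occupancy_fraction=1.0)
    assert exposure_rate(full) == pytest.approx(0.2064)
    with pytest.raises(ValidationError):
        ExposureConstants(wl_per_pci=0.0)


def test_lifetime_risk_male_ever_at_unit_concentration(constants, unit_risks):
    risk = lifetime_risk_for_status(1.0, "male", "ever", constants,
                                    unit_risks)
    assert risk == pytest.approx(1.0 * 0.14448 * 75 * 0.00106, rel=1e-12)
    # agrees with the hand product using the rounded printed rate 0.144
    assert risk == pytest.approx(0.011448, rel=4e-3)


def test_lifetime_risk_zero_concentration(constants, unit_risks):
    for sex in ("male", "female"):
        for status in ("ever", "never"):
            assert lifetime_risk_for_status(0.0, sex, status, constants,
                                            unit_risks) == 0.0
    with pytest.raises(ValidationError):
        lifetime_risk_for_status(-1.0, "male", "ever", constants, unit_risks)


def test_general_population_benchmark(constants, unit_risks):
    """1.25 pCi/L at the general-population unit risk reproduces the
    published national average lifetime risk of 0.73%."""
    risk = (1.25 * exposure_rate(constants)
            * constants.exposure_duration_years
            * unit_risks.general_population)
    assert round(100 * risk, 2) == 0.73


def test_risk_linear_in_concentration_and_duration(constants, unit_risks):
    r1 = lifetime_risk_for_status(1.0, "female", "never", constants,
                                  unit_risks)
    r3 = lifetime_risk_for_status(3.0, "female", "never", constants,
                                  unit_risks)
    assert r3 == pytest.approx(3 * r1, rel=1e-12)
    c2 = ExposureConstants(exposure_duration_years=150)
    assert lifetime_risk_for_status(1.0, "female", "never", c2, unit_risks) \
        == pytest.approx(2 * r1, rel=1e-12)


def test_absurd_input_clips_below_one(constants, unit_risks):
    with pytest.warns(UserWarning, match="clipping"):
        risk = lifetime_risk_for_status(1e6, "male", "ever", constants,
                                        unit_risks)
    assert 0 < risk < 1


def test_bin_risk_single_branch_product(radon_params, housing_params,
                                        smoking_params, constants,
                                        unit_risks):
    """Forcing one house type, p_ever=0 and C=1 pCi/L reduces the chain to
    the bare product of constants: 0.144... x 75 x UR(female, never)."""
    from radonrisk.parameters import HousingModelParams, SmokingModelParams

    # intercepts at -inf-ish for all but the reference: all mass on basement
    hp = HousingModelParams(
        intercepts={o: -1e3 for o in housing_params.intercepts},
        coefs={k: 0.0 for k in housing_params.coefs})
    sp = SmokingModelParams(intercept=-1e3, fixed_coefs={
        k: 0.0 for k in smoking_params.fixed_coefs}, var_state=0,
        var_state_black_slope=0, cov_state_blackslope=0, var_cbsa=0,
        var_household=0)
    rp = radon_params
    rp0 = type(rp)(intercept=0.0, region_coefs={k: 0.0 for k in
                                                rp.region_coefs},
                   geo_coefs={k: 0.0 for k in rp.geo_coefs}, hdd_coef=0.0,
                   diurnal_coef=0.0,
                   housetype_coefs={k: 0.0 for k in rp.housetype_coefs})
    res = bin_risk(_bin(), _ctx(), rp0, hp, sp, constants, unit_risks)
    assert res.expected_concentration == pytest.approx(1.0, rel=1e-9)
    assert res.p_ever_smoking == pytest.approx(0.0, abs=1e-12)
    assert res.lifetime_risk == pytest.approx(0.14448 * 75 * 0.000161,
                                              rel=1e-6)
    # hand product with the rounded printed rate 0.144
    assert res.lifetime_risk == pytest.approx(0.0017388, rel=4e-3)


def test_ever_never_risk_ratio_is_unit_risk_ratio(constants, unit_risks):
    r_ever = lifetime_risk_for_status(2.0, "male", "ever", constants,
                                      unit_risks)
    r_never = lifetime_risk_for_status(2.0, "male", "never", constants,
                                       unit_risks)
    assert r_ever / r_never == pytest.approx(0.00106 / 0.000174, rel=1e-12)
    assert r_ever / r_never == pytest.approx(6.092, abs=2e-3)


def _enumeration_oracle(res, bin, constants, unit_risks):
    """Exhaustive sum over (house type x smoking status) combinations."""
    total = 0.0
    for ht in HOUSE_TYPES:
        for status, p_s in (("ever", res.p_ever_smoking),
                            ("never", 1 - res.p_ever_smoking)):
            joint = res.housetype_probs[ht] * p_s
            risk = (res.concentration_by_type[ht] * exposure_rate(constants)
                    * constants.exposure_duration_years
                    * unit_risks.lookup(bin.sex, status))
            total += joint * risk
    return total


def test_factorized_risk_equals_enumeration(radon_params, housing_params,
                                            smoking_params, constants,
                                            unit_risks):
    rng = np.random.default_rng(12)
    from radonrisk import vocab
    for _ in range(50):
        b = _bin(age_group=rng.choice(vocab.AGE_GROUPS),
                 sex=rng.choice(vocab.SEXES), race=rng.choice(vocab.RACES),
                 poverty=rng.choice(vocab.POVERTY))
        ctx = _ctx(region=rng.choice(vocab.REGIONS),
                   geo_potential=rng.choice(vocab.GEO_POTENTIAL),
                   heating_infiltration_degree_days=rng.uniform(0, 9000),
                   avg_diurnal_swing=rng.uniform(10, 35),
                   radon_state_residual=rng.normal(0, 0.2),
                   smoking_state_residual=rng.normal(0, 0.2))
        res = bin_risk(b, ctx, radon_params, housing_params, smoking_params,
                       constants, unit_risks)
        assert abs(res.lifetime_risk
                   - _enumeration_oracle(res, b, constants, unit_risks)) \
            <= 1e-12


def _result(county, state, count, risk, conc=1.0, p=0.4):
    b = DemographicBin(county, state, "45-54", "female", "white", "above",
                       count)
    probs = dict.fromkeys(HOUSE_TYPES, 0.2)
    concs = dict.fromkeys(HOUSE_TYPES, conc)
    return BinRiskResult(bin=b, p_ever_smoking=p, housetype_probs=probs,
                         concentration_by_type=concs,
                         expected_concentration=conc, lifetime_risk=risk)


def test_weighted_mean_hand_example():
    res = [_result("C1", "S1", 100, 0.004), _result("C1", "S1", 300, 0.008)]
    out = aggregate(res, "county")
    assert len(out) == 1
    assert out["mean_risk"].iloc[0] == pytest.approx(0.007, rel=1e-12)
    assert out["population"].iloc[0] == 400


def test_single_bin_county_equals_bin():
    res = [_result("C1", "S1", 50, 0.003, conc=1.7, p=0.35)]
    out = aggregate(res, "county")
    assert out["mean_risk"].iloc[0] == 0.003
    assert out["mean_concentration"].iloc[0] == 1.7
    assert out["mean_p_ever_smoking"].iloc[0] == 0.35


def test_bin_split_invariance():
    whole = [_result("C1", "S1", 200, 0.004), _result("C2", "S1", 100, 0.01)]
    split = [_result("C1", "S1", 100, 0.004), _result("C1", "S1", 100, 0.004),
             _result("C2", "S1", 100, 0.01)]
    for level in ("county", "state", "national"):
        a = aggregate(whole, level).reset_index(drop=True)
        b = aggregate(split, level).reset_index(drop=True)
        assert np.allclose(a["mean_risk"], b["mean_risk"])
        assert (a["population"] == b["population"]).all()


@given(st.lists(st.tuples(st.integers(1, 5), st.integers(1, 1000),
                          st.floats(0.0005, 0.05)),
                min_size=2, max_size=12))
@settings(max_examples=50, deadline=None)
def test_aggregates_bounded_by_member_extremes(groups):
    res = [_result(f"C{c}", "S1", n, r) for c, n, r in groups]
    for level in ("county", "state", "national"):
        out = aggregate(res, level)
        risks = [r for _, _, r in groups]
        assert (out["mean_risk"] >= min(risks) - 1e-15).all()
        assert (out["mean_risk"] <= max(risks) + 1e-15).all()


def test_zero_population_group_excluded_with_warning():
    res = [_result("C1", "S1", 0, 0.004), _result("C2", "S1", 10, 0.01)]
    with pytest.warns(UserWarning, match="zero population"):
        out = aggregate(res, "county")
    assert list(out["county_id"]) == ["C2"]
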