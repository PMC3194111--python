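"""Lifetime radon lung-cancer risk engine and population aggregation.

The risk algorithm converts an annual-average radon concentration C (pCi/L)
into cumulative exposure at a rate of

    wl_per_pci x wlm_per_wl_year x occupancy_fraction  ~ 0.144 WLM/yr per pCi/L

over a fixed residential exposure duration D (default 75 years), and
multiplies by the sex- and smoking-status-specific unit risk UR (lifetime
fatal lung-cancer probability per WLM):

    risk = C x rate x D x UR(sex, status).

Per demographic bin the three regression models supply the ever-smoking
probability p, the five house-type probabilities P_h and the per-type
concentrations C_h.  Assuming smokers and non-smokers are distributed
identically across house types within a bin, the expectation over the
5 x 2 (house type x smoking status) combinations factorises exactly:

    risk = (sum_h P_h C_h) x rate x D x [p UR_ever + (1-p) UR_never].

Risks are clipped to [0, 1) with a warning: the linear excess-risk formula
is an approximation that can exceed 1 for extreme inputs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import vocab
from .exceptions import ValidationError
from .housing import housing_probabilities
from .parameters import ExposureConstants, UnitRiskFactors
from .radon import predict_concentration
from .smoking import predict_ever_smoking
from .types import BinRiskResult, CountyContext, DemographicBin


def exposure_rate(constants: ExposureConstants) -> float:
    """Exposure rate in WLM per year per pCi/L of radon gas."""
    return (constants.wl_per_pci * constants.wlm_per_wl_year
            * constants.occupancy_fraction)


def _clip_risk(risk: float) -> float:
    if risk >= 1.0:
        warnings.warn(
            f"computed lifetime risk {risk:.3g} >= 1; clipping to just "
            "below 1 (linear excess-risk formula outside its valid range)",
            stacklevel=3)
        return np.nextafter(1.0, 0.0)
    return risk


def lifetime_risk_for_status(concentration: float, sex: str,
                             smoking_status: str,
                             constants: ExposureConstants,
                             unit_risks: UnitRiskFactors) -> float:
    """Lifetime fatal lung-cancer risk at a constant concentration."""
    if concentration < 0:
        raise ValidationError(
            f"concentration must be >= 0, got {concentration}")
    ur = unit_risks.lookup(sex, smoking_status)
    risk = (concentration * exposure_rate(constants)
            * constants.exposure_duration_years * ur)
    return _clip_risk(risk)


def bin_risk(bin: DemographicBin, context: CountyContext, radon_params,
             housing_params, smoking_params,
             constants: ExposureConstants | None = None,
             unit_risks: UnitRiskFactors | None = None,
             include_residuals: bool = True,
             islander_as: str = "other") -> BinRiskResult:
    """Run the full three-model prediction chain for one bin."""
    constants = constants if constants is not None else ExposureConstants()
    unit_risks = unit_risks if unit_risks is not None else UnitRiskFactors()
    try:
        p_ever = predict_ever_smoking(bin, context, smoking_params)
    except ValidationError as exc:
        raise ValidationError(f"smoking prediction failed: {exc}") from exc
    try:
        probs = housing_probabilities(bin, context.region, housing_params,
                                      islander_as=islander_as)
    except (ValidationError, KeyError) as exc:
        raise ValidationError(f"housing prediction failed: {exc}") from exc
    try:
        concs = {ht: predict_concentration(context, ht, radon_params,
                                           include_residuals=include_residuals)
                 for ht in vocab.HOUSE_TYPES}
    except ValidationError as exc:
        raise ValidationError(f"radon prediction failed: {exc}") from exc
    expected_c = sum(probs[ht] * concs[ht] for ht in vocab.HOUSE_TYPES)
    ur_mix = (p_ever * unit_risks.lookup(bin.sex, "ever")
              + (1.0 - p_ever) * unit_risks.lookup(bin.sex, "never"))
    risk = (expected_c * exposure_rate(constants)
            * constants.exposure_duration_years * ur_mix)
    return BinRiskResult(
        bin=bin, p_ever_smoking=p_ever, housetype_probs=probs,
        concentration_by_type=concs, expected_concentration=expected_c,
        lifetime_risk=_clip_risk(risk))


def compute_bin_risks(bins, contexts, radon_params, housing_params,
                      smoking_params, constants=None, unit_risks=None,
                      include_residuals: bool = True) -> list[BinRiskResult]:
    """Apply :func:`bin_risk` to every bin, resolving county contexts."""
    out = []
    for b in bins:
        if b.county_id not in contexts:
            raise ValidationError(f"no context for county {b.county_id!r}")
        out.append(bin_risk(b, contexts[b.county_id], radon_params,
                            housing_params, smoking_params, constants,
                            unit_risks, include_residuals))
    return out


_LEVEL_KEYS = {"county": ["state_id", "county_id"], "state": ["state_id"],
               "national": []}


def aggregate(results, level: str = "county") -> pd.DataFrame:
    """Population-weighted mean risk, concentration and smoking prevalence.

    Weights are bin population counts.  Groups whose total count is zero
    are excluded with a warning.
    """
    if level not in _LEVEL_KEYS:
        raise ValidationError(f"level must be county, state or national, "
                              f"got {level!r}")
    df = pd.DataFrame([{
        "county_id": r.bin.county_id, "state_id": r.bin.state_id,
        "count": r.bin.count, "risk": r.lifetime_risk,
        "concentration": r.expected_concentration,
        "p_ever_smoking": r.p_ever_smoking} for r in results])
    keys = _LEVEL_KEYS[level]
    if not keys:
        df = df.assign(_nation="national")
        keys = ["_nation"]
    rows = []
    for key, g in df.groupby(keys):
        pop = g["count"].sum()
        if pop == 0:
            warnings.warn(f"group {key!r} has zero population; excluded",
                          stacklevel=2)
            continue
        w = g["count"] / pop
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row["population"] = int(pop)
        for col in ("risk", "concentration", "p_ever_smoking"):
            row[f"mean_{col}"] = float((w * g[col]).sum())
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.drop(columns="_nation", errors="ignore")


def county_summary(results) -> dict:
    """Unweighted summary of county-average risks (mean/median/sd/range)."""
    county = aggregate(results, "county")
    r = county["mean_risk"]
    return {"n_counties": int(len(county)), "mean": float(r.mean()),
            "median": float(r.median()), "sd": float(r.std(ddof=1)),
            "min": float(r.min()), "max": float(r.max())}
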