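"""Multinomial logistic model of the five-category house type.

House type (detached with basement — the reference —, attached/other unit,
detached with crawl space, detached slab-on-grade, other detached) is
predicted from individual demographics (poverty, sex, race, age group) and
census region.  The model is single-level by construction: house type is
constant within a household, so household clustering cannot be modelled,
and region is the only geographic covariate available in the source survey.

Prediction is the softmax over the reference's zero linear predictor and
the four outcome-specific predictors.  The smoking model distinguishes a
Pacific-islander race level that the housing survey does not; for housing
prediction it maps to the residual "other" category by default
(configurable via ``islander_as``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import vocab
from .exceptions import ConvergenceError, ValidationError
from .parameters import HousingModelParams

REQUIRED_COLUMNS = ("house_type", "poverty", "sex", "race", "region",
                    "age_group")

_TERMS = (
    ("poverty", ("below",), vocab.POVERTY, "poverty"),
    ("sex", ("male",), vocab.SEXES, "sex"),
    ("race", ("black", "asian", "other", "native"), vocab.HOUSING_RACES,
     "race"),
    ("region", ("Northeast", "Midwest", "West"), vocab.REGIONS, "region"),
    ("age", ("<18", "18-24", "25-34", "35-44", "55-64", "65-74", "75+"),
     vocab.HOUSING_AGE_GROUPS, "age_group"),
)


def _resolve_race(race: str, islander_as: str) -> str:
    if race == "islander":
        if islander_as not in vocab.HOUSING_RACES:
            raise ValidationError(
                f"islander_as must be a housing race level, got {islander_as!r}")
        return islander_as
    return race


def housing_linear_predictors(bin, region: str, params: HousingModelParams,
                              islander_as: str = "other") -> dict:
    """Log-odds of each non-reference house type for one demographic profile.

    ``bin`` needs attributes ``poverty``, ``sex``, ``race`` and
    ``age_group``; the reference outcome's linear predictor is implicitly 0.
    """
    if region not in vocab.REGIONS:
        raise ValidationError(f"unknown region {region!r}")
    if bin.age_group not in vocab.HOUSING_AGE_GROUPS:
        raise ValidationError(f"unknown age group {bin.age_group!r}")
    race = _resolve_race(bin.race, islander_as)
    active = []
    if bin.poverty == "below":
        active.append(("poverty", "below"))
    if bin.sex == "male":
        active.append(("sex", "male"))
    if race != vocab.RACE_REF:
        active.append(("race", race))
    if region != vocab.HOUSING_REGION_REF:
        active.append(("region", region))
    if bin.age_group != vocab.AGE_REF:
        active.append(("age", bin.age_group))
    out = {}
    for outcome in params.outcomes:
        eta = params.intercepts[outcome]
        for term, level in active:
            eta += params.coefs[(outcome, term, level)]
        out[outcome] = eta
    return out


def housing_probabilities(bin, region: str, params: HousingModelParams,
                          islander_as: str = "other") -> dict:
    """Probability of each of the five house types (sums to 1)."""
    etas = housing_linear_predictors(bin, region, params, islander_as)
    keys = [params.reference] + list(params.outcomes)
    vals = np.array([0.0] + [etas[o] for o in params.outcomes])
    vals -= vals.max()  # softmax shift invariance
    ex = np.exp(vals)
    probs = ex / ex.sum()
    return dict(zip(keys, probs))


def _build_design(df: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    for term, levels, allowed, col in _TERMS:
        bad = set(df[col]) - set(allowed)
        if bad:
            raise ValidationError(
                f"unknown {col} level(s) {sorted(bad)} in housing data")
        for lvl in levels:
            X[f"{term}:{lvl}"] = (df[col] == lvl).astype(float)
    return X


class HouseTypeModel:
    """Multinomial logistic regression of house type on demographics.

    Parameters
    ----------
    data : DataFrame
        One row per person with columns ``house_type, poverty, sex, race,
        region, age_group``.  All five house types must be present.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"housing table missing columns {missing}")
        present = set(data["house_type"])
        bad = present - set(vocab.HOUSE_TYPES)
        if bad:
            raise ValidationError(f"unknown house type(s) {sorted(bad)}")
        absent = set(vocab.HOUSE_TYPES) - present
        if absent:
            raise ValidationError(
                f"house type(s) {sorted(absent)} absent from data; all five "
                "outcomes are required (degenerate design)")
        self.data = data
        self.exog = _build_design(data)
        # reference outcome first so its coefficients are the zero baseline
        order = [vocab.HOUSE_TYPE_REF] + list(vocab.HOUSE_TYPE_OUTCOMES)
        self.endog = pd.Categorical(data["house_type"], categories=order)
        self._outcome_order = order

    @classmethod
    def from_csv(cls, path) -> "HouseTypeModel":
        return cls(pd.read_csv(path))

    def fit(self, maxiter: int = 1000):
        """Maximum-likelihood fit; returns :class:`HouseTypeResults`."""
        model = sm.MNLogit(self.endog.codes, self.exog)
        with np.errstate(over="ignore"):
            res = model.fit(method="lbfgs", maxiter=maxiter, disp=False)
        biggest = float(np.abs(res.params.values).max())
        if not res.mle_retvals.get("converged", False) or biggest > 25:
            raise ConvergenceError(
                "multinomial fit did not converge (possible separation); "
                f"largest |coef| = {biggest:.2f}")
        return HouseTypeResults(self, res)


class HouseTypeResults:
    """Fitted house-type model with statsmodels-style accessors."""

    def __init__(self, model: HouseTypeModel, sm_result):
        self.model = model
        self._res = sm_result
        self.llf = float(sm_result.llf)
        # columns of sm_result.params are outcomes 1..4 in category order
        self._est = pd.DataFrame(
            sm_result.params.values, index=model.exog.columns,
            columns=model._outcome_order[1:])
        self._bse = pd.DataFrame(
            sm_result.bse.values, index=model.exog.columns,
            columns=model._outcome_order[1:])

    @property
    def params(self) -> HousingModelParams:
        intercepts, coefs, ses = {}, {}, {}
        for out in vocab.HOUSE_TYPE_OUTCOMES:
            intercepts[out] = float(self._est.loc["Intercept", out])
            ses[(out, "intercept", "")] = float(self._bse.loc["Intercept", out])
            for term, levels, _, _ in _TERMS:
                for lvl in levels:
                    coefs[(out, term, lvl)] = float(
                        self._est.loc[f"{term}:{lvl}", out])
                    ses[(out, term, lvl)] = float(
                        self._bse.loc[f"{term}:{lvl}", out])
        return HousingModelParams(intercepts=intercepts, coefs=coefs,
                                  ses=ses, llf=self.llf)

    def summary(self) -> str:
        lines = ["Multinomial house-type model (MLE)",
                 f"observations: {len(self.model.data)}   "
                 f"log-likelihood: {self.llf:.2f}", ""]
        for out in vocab.HOUSE_TYPE_OUTCOMES:
            lines.append(f"-- outcome {out} (vs {vocab.HOUSE_TYPE_REF})")
            for name in self.model.exog.columns:
                lines.append(f"  {name:<22}{self._est.loc[name, out]:>10.4f}"
                             f"{self._bse.loc[name, out]:>10.4f}")
        return "\n".join(lines)
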