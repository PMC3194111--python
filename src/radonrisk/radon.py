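"""Log-linear model of annual-average living-area radon concentration.

Indoor radon concentrations are approximately lognormal, so the model is
linear on log(pCi/L): census region, county geological radon potential
(USGS Low/Medium/High summary score), two county meteorological variables
(annual heating-infiltration degree-days and average diurnal temperature
swing) and a five-category house type, with nested random intercepts for
state, primary sampling unit (county) and secondary sampling unit (census
tract) reflecting the survey's four-level clustering.

Prediction exponentiates the linear predictor (a geometric-scale
prediction); no lognormal mean correction (+ total variance / 2) is applied
by default because the downstream risk chain sums fixed effects and
residuals only.  Pass ``mean_correction=True`` to
:func:`predict_concentration` to add half the total random variance before
exponentiating.

Fitting is REML via :class:`statsmodels` ``MixedLM`` with variance
components for the two intermediate levels; the noiseless degenerate case
(all level variances zero) falls back to ordinary least squares.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import vocab
from .exceptions import ConvergenceError, ValidationError
from .parameters import RadonModelParams
from .types import CountyContext

REQUIRED_COLUMNS = ("house_id", "ssu_id", "psu_id", "state_id", "house_type",
                    "region", "geo_potential", "hdd", "diurnal_swing",
                    "concentration")

#: design columns of the fixed-effect part, in fitting order
_FE_TERMS = (
    ("region", "Northeast"), ("region", "South"), ("region", "West"),
    ("geo_potential", "Medium"), ("geo_potential", "High"),
    ("hdd", ""), ("diurnal_swing", ""),
    ("house_type", "attached"), ("house_type", "crawl_space"),
    ("house_type", "slab"), ("house_type", "other_detached"),
)


def preprocess_concentration(raw, floor: float = 0.1):
    """Clamp measured concentrations to a positive floor.

    Survey instruments can record non-positive values; a configurable floor
    (default 0.1 pCi/L, about the minimal outdoor concentration) keeps the
    log transform defined.  Accepts scalars or arrays.
    """
    if floor <= 0:
        raise ValidationError(f"floor must be positive, got {floor}")
    arr = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("raw concentration must be finite")
    out = np.maximum(arr, floor)
    return float(out) if np.isscalar(raw) else out


def radon_linear_predictor(context: CountyContext, house_type: str,
                           params: RadonModelParams,
                           include_residuals: bool = False) -> float:
    """Linear predictor on the log(pCi/L) scale for one county/house type."""
    if house_type not in vocab.HOUSE_TYPES:
        raise ValidationError(f"unknown house type {house_type!r}")
    if context.geo_potential not in params.geo_coefs:
        raise ValidationError(
            f"unknown geological potential class {context.geo_potential!r}")
    lp = (params.intercept
          + params.region_coefs[context.region]
          + params.geo_coefs[context.geo_potential]
          + params.hdd_coef * context.heating_infiltration_degree_days
          + params.diurnal_coef * context.avg_diurnal_swing
          + params.housetype_coefs[house_type])
    if include_residuals:
        lp += context.radon_state_residual + context.radon_county_residual
    return lp


def predict_concentration(context: CountyContext, house_type: str,
                          params: RadonModelParams,
                          include_residuals: bool = False,
                          mean_correction: bool = False) -> float:
    """Predicted radon concentration in pCi/L (geometric-scale by default)."""
    lp = radon_linear_predictor(context, house_type, params, include_residuals)
    if mean_correction:
        lp += 0.5 * sum(params.variance_components.values())
    return math.exp(lp)


def _build_design(df: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    for term, level in _FE_TERMS:
        if level:
            X[f"{term}:{level}"] = (df[term] == level).astype(float)
        else:
            X[term] = df[term].astype(float)
    return X


def _check_nesting(df: pd.DataFrame) -> None:
    for child, parent in (("house_id", "ssu_id"), ("ssu_id", "psu_id"),
                          ("psu_id", "state_id")):
        n_parents = df.groupby(child)[parent].nunique()
        if (n_parents > 1).any():
            bad = n_parents[n_parents > 1].index[0]
            raise ValidationError(
                f"{child} {bad!r} maps to multiple {parent} values; "
                "levels must be strictly nested")
    for col in ("state_id", "psu_id", "ssu_id", "house_id"):
        if df[col].nunique() < 2:
            raise ValidationError(f"need at least 2 distinct {col} values")


class RadonConcentrationModel:
    """Nested random-intercept model of log radon concentration.

    Parameters
    ----------
    data : DataFrame
        One row per housing unit with columns
        ``house_id, ssu_id, psu_id, state_id, house_type, region,
        geo_potential, hdd, diurnal_swing, concentration``.
        Concentrations must be strictly positive (see
        :func:`preprocess_concentration`).
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"measurement table missing columns {missing}")
        data = data.copy()
        if (data["concentration"] <= 0).any():
            raise ValidationError(
                "concentrations must be strictly positive; run "
                "preprocess_concentration first")
        for term, level in _FE_TERMS:
            if level and not (data[term] == level).any():
                raise ValidationError(
                    f"categorical level {level!r} of {term!r} absent from "
                    "data; design would be singular")
        _check_nesting(data)
        data["log_concentration"] = np.log(data["concentration"].astype(float))
        self.data = data
        self.exog = _build_design(data)
        self.endog = data["log_concentration"]

    @classmethod
    def from_csv(cls, path) -> "RadonConcentrationModel":
        return cls(pd.read_csv(path))

    def fit(self, reml: bool = True, maxiter: int = 200):
        """Estimate fixed effects and the four level variances.

        Returns a :class:`RadonConcentrationResults`.
        """
        # degenerate noiseless data: OLS reproduces the fixed effects exactly
        ols = sm.OLS(self.endog, self.exog).fit()
        if float(np.mean(ols.resid ** 2)) < 1e-12:
            return RadonConcentrationResults(
                self, ols.params, ols.bse,
                vc={"state": 0.0, "psu": 0.0, "ssu": 0.0, "residual": 0.0},
                llf=float(ols.llf), converged=True)
        df = self.data.assign(**{c: self.exog[c] for c in self.exog.columns
                                 if c != "Intercept"})
        rename = {c: c.replace(":", "_").replace("-", "_").replace("<", "lt")
                  for c in self.exog.columns if c != "Intercept"}
        df = df.rename(columns=rename)
        rhs = " + ".join(rename.values())
        model = sm.MixedLM.from_formula(
            f"log_concentration ~ {rhs}", data=df, groups="state_id",
            re_formula="1",
            vc_formula={"psu": "0 + C(psu_id)", "ssu": "0 + C(ssu_id)"},
        )
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "bfgs", "powell", "nm"):
                try:
                    cand = model.fit(reml=reml, maxiter=maxiter,
                                     method=method)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if cand.converged:
                    res = cand
                    break
        if res is None:
            raise ConvergenceError("mixed-model estimation did not converge "
                                   "under any optimizer")
        order = ["Intercept"] + [rename[c] for c in self.exog.columns
                                 if c != "Intercept"]
        back = {v: k for k, v in rename.items()}
        back["Intercept"] = "Intercept"
        fe = pd.Series({back[k]: res.fe_params[k] for k in order})
        bse = pd.Series({back[k]: res.bse_fe[k] for k in order})
        vc = {
            "state": float(res.cov_re.iloc[0, 0]),
            "psu": float(res.vcomp[0]),
            "ssu": float(res.vcomp[1]),
            "residual": float(res.scale),
        }
        return RadonConcentrationResults(self, fe, bse, vc,
                                         llf=float(res.llf), converged=True)


class RadonConcentrationResults:
    """Fitted radon model: estimates, standard errors, variances, summary."""

    def __init__(self, model, fe_params, bse, vc, llf, converged):
        self.model = model
        self.fe_params = fe_params
        self.bse = bse
        self.variance_components = vc
        self.llf = llf
        self.converged = converged

    @property
    def params(self) -> RadonModelParams:
        """Estimates as a reusable parameter bundle."""
        fe, se = self.fe_params, self.bse
        ses = {"intercept": se["Intercept"]}
        for term, level in _FE_TERMS:
            key = f"{term}:{level}" if level else term
            ses[key] = se[key]
        return RadonModelParams(
            intercept=fe["Intercept"],
            region_coefs={lvl: fe[f"region:{lvl}"]
                          for lvl in ("Northeast", "South", "West")},
            geo_coefs={lvl: fe[f"geo_potential:{lvl}"]
                       for lvl in ("Medium", "High")},
            hdd_coef=fe["hdd"], diurnal_coef=fe["diurnal_swing"],
            housetype_coefs={lvl: fe[f"house_type:{lvl}"]
                             for lvl in vocab.HOUSE_TYPE_OUTCOMES},
            variance_components=dict(self.variance_components),
            ses=ses, llf=self.llf,
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        """Fixed-effect fitted values on the log scale."""
        return self.model.exog.to_numpy() @ self.fe_params.to_numpy()

    def summary(self) -> str:
        lines = ["Log-linear radon concentration model (REML)",
                 f"observations: {len(self.model.data)}   "
                 f"log-likelihood: {self.llf:.2f}", "",
                 f"{'term':<28}{'estimate':>12}{'se':>10}"]
        for name in self.fe_params.index:
            lines.append(f"{name:<28}{self.fe_params[name]:>12.4f}"
                         f"{self.bse[name]:>10.4f}")
        lines.append("")
        for lvl, v in self.variance_components.items():
            lines.append(f"variance({lvl}):{v:>12.4f}")
        return "\n".join(lines)
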