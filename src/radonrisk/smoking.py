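"""Multilevel logistic model of ever-smoking in adults.

Ever-smoking (current or former) is the outcome because the radon unit risk
differs between ever- and never-smokers.  Fixed effects: sex, age group,
poverty, race, race x male interactions, state cigarette excise tax,
previous state smoking prevalence, indoor-smoking-restriction legislation
and two CBSA indicators.  Random structure: a state intercept with a
correlated state-level random slope for Black race, a CBSA intercept and a
household intercept.

Prediction for a demographic bin sums fixed effects plus state and CBSA
residuals (and the state black-slope residual for Black bins); the
household random effect is never included and no marginalisation correction
is applied, so predictions are conditional (median-household) probabilities.
:func:`marginal_prevalence` quantifies the resulting attenuation gap.

Fitting delegates to lme4's Laplace-approximation ``glmer`` through a
bundled R script; R with lme4 must be on PATH.
"""

from __future__ import annotations

import json
import math
import shutil
import subprocess
import tempfile
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, roots_hermitenorm

from . import vocab
from .exceptions import ConvergenceError, ValidationError
from .parameters import SmokingModelParams
from .types import CountyContext, DemographicBin

REQUIRED_COLUMNS = ("household_id", "cbsa_id", "state_id", "sex", "age_group",
                    "poverty", "race", "income_not_reported", "state_tax",
                    "prev_state_prevalence", "indoor_restrictions",
                    "cbsa_poverty_above_median", "cbsa_nonmetropolitan",
                    "ever_smoker")


def smoking_linear_predictor(bin: DemographicBin, context: CountyContext,
                             params: SmokingModelParams,
                             income_not_reported: bool = False) -> float:
    """Logit of ever-smoking for one bin in one county context.

    Includes state and CBSA residuals and, for Black bins, the state-level
    random slope for Black race; excludes the household random effect.
    ``income_not_reported`` stays False for census-derived bins (census
    poverty cross-tabulations have no such level).
    """
    coefs = params.fixed_coefs
    lp = params.intercept
    if bin.sex == "male":
        lp += coefs["male"]
    if bin.age_group != vocab.AGE_REF:
        lp += coefs[f"age:{bin.age_group}"]
    if bin.poverty == "below":
        lp += coefs["poverty:below"]
    if income_not_reported:
        lp += coefs["income_not_reported"]
    if bin.race != vocab.RACE_REF:
        lp += coefs[f"race:{bin.race}"]
        if bin.sex == "male":
            lp += coefs[f"race_male:{bin.race}"]
    lp += coefs["state_tax"] * context.state_cigarette_tax
    lp += coefs["prev_state_prevalence"] * context.prev_state_prevalence_2003
    lp += coefs["indoor_restrictions"] * context.indoor_restriction_flag
    lp += coefs["cbsa_poverty_above_median"] * context.cbsa_poverty_above_median
    lp += coefs["cbsa_nonmetropolitan"] * context.cbsa_nonmetropolitan
    lp += context.smoking_state_residual + context.smoking_cbsa_residual
    if bin.race == "black":
        lp += context.smoking_state_black_slope
    return lp


def predict_ever_smoking(bin: DemographicBin, context: CountyContext,
                         params: SmokingModelParams,
                         income_not_reported: bool = False) -> float:
    """Predicted probability of ever-smoking, in (0, 1)."""
    return float(expit(smoking_linear_predictor(
        bin, context, params, income_not_reported)))


def marginal_prevalence(lp, var_household: float, n_nodes: int = 40):
    """Population-average prevalence E[expit(lp + u)], u ~ N(0, var).

    Gauss-Hermite quadrature over the household random effect.  The gap
    ``expit(lp) - marginal_prevalence(lp, var)`` is the attenuation incurred
    by predicting from fixed effects and area residuals only.
    """
    if var_household < 0:
        raise ValidationError("var_household must be >= 0")
    nodes, weights = roots_hermitenorm(n_nodes)
    weights = weights / weights.sum()
    lp = np.asarray(lp, dtype=float)
    vals = expit(lp[..., None] + math.sqrt(var_household) * nodes)
    out = vals @ weights
    return float(out) if out.ndim == 0 else out


def attenuation_diagnostic(lp, params: SmokingModelParams) -> dict:
    """Conditional-vs-marginal gap at a given linear predictor."""
    cond = float(expit(lp))
    marg = float(marginal_prevalence(lp, params.var_household))
    return {"conditional": cond, "marginal": marg, "gap": cond - marg}


_AGE_LEVELS = tuple(a for a in vocab.AGE_GROUPS if a != vocab.AGE_REF)
_RACE_LEVELS = tuple(r for r in vocab.RACES if r != vocab.RACE_REF)


def _build_design(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric fixed-effect design plus grouping columns for the R backend."""
    bad = set(df["race"]) - set(vocab.RACES)
    if bad:
        raise ValidationError(f"unknown race level(s) {sorted(bad)}")
    bad = set(df["age_group"]) - set(vocab.AGE_GROUPS)
    if bad:
        raise ValidationError(f"unknown age group(s) {sorted(bad)}")
    X = pd.DataFrame(index=df.index)
    X["y"] = df["ever_smoker"].astype(int)
    male = (df["sex"] == "male").astype(int)
    X["male"] = male
    for lvl in _AGE_LEVELS:
        X[f"age_{lvl}".replace("-", "_").replace("+", "plus")] = (
            df["age_group"] == lvl).astype(int)
    X["poverty_below"] = (df["poverty"] == "below").astype(int)
    X["income_not_reported"] = df["income_not_reported"].astype(int)
    for lvl in _RACE_LEVELS:
        X[f"race_{lvl}"] = (df["race"] == lvl).astype(int)
    for lvl in _RACE_LEVELS:
        X[f"racemale_{lvl}"] = ((df["race"] == lvl) & (male == 1)).astype(int)
    for col in ("state_tax", "prev_state_prevalence", "indoor_restrictions",
                "cbsa_poverty_above_median", "cbsa_nonmetropolitan"):
        X[col] = df[col].astype(float)
    X["black"] = (df["race"] == "black").astype(int)
    X["state"] = pd.factorize(df["state_id"])[0]
    X["cbsa"] = pd.factorize(df["cbsa_id"])[0]
    X["household"] = pd.factorize(df["household_id"])[0]
    return X


_R_NAME_MAP = {"(Intercept)": "intercept", "male": "male",
               "poverty_below": "poverty:below",
               "income_not_reported": "income_not_reported",
               "state_tax": "state_tax",
               "prev_state_prevalence": "prev_state_prevalence",
               "indoor_restrictions": "indoor_restrictions",
               "cbsa_poverty_above_median": "cbsa_poverty_above_median",
               "cbsa_nonmetropolitan": "cbsa_nonmetropolitan"}
for _lvl in _AGE_LEVELS:
    _R_NAME_MAP[f"age_{_lvl}".replace("-", "_").replace("+", "plus")] = \
        f"age:{_lvl}"
for _lvl in _RACE_LEVELS:
    _R_NAME_MAP[f"race_{_lvl}"] = f"race:{_lvl}"
    _R_NAME_MAP[f"racemale_{_lvl}"] = f"race_male:{_lvl}"


class EverSmokingModel:
    """Three-level random-effects logistic model of ever-smoking.

    Parameters
    ----------
    data : DataFrame
        One row per person with the columns in :data:`REQUIRED_COLUMNS`.
        Households must nest within CBSAs and CBSAs within states.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"smoking table missing columns {missing}")
        for child, parent in (("household_id", "cbsa_id"),
                              ("cbsa_id", "state_id")):
            n_par = data.groupby(child)[parent].nunique()
            if (n_par > 1).any():
                bad = n_par[n_par > 1].index[0]
                raise ValidationError(
                    f"{child} {bad!r} maps to multiple {parent} values; "
                    "identifiers must be nested")
        if data["state_id"].nunique() < 2:
            raise ValidationError("need at least 2 states")
        y = data["ever_smoker"].astype(int)
        if y.nunique() < 2:
            raise ConvergenceError(
                "outcome has no variation (all zeros or all ones); the "
                "logistic likelihood is degenerate")
        self.data = data
        self.design = _build_design(data)

    @classmethod
    def from_csv(cls, path) -> "EverSmokingModel":
        return cls(pd.read_csv(path))

    def fit(self, rscript: str | None = None):
        """Laplace-approximation fit via lme4; returns EverSmokingResults."""
        exe = rscript or shutil.which("Rscript")
        if exe is None:
            raise RuntimeError(
                "Rscript not found on PATH; fitting the multilevel smoking "
                "model requires R with lme4")
        script = resources.files("radonrisk.r") / "fit_smoking_glmer.R"
        with tempfile.TemporaryDirectory() as tmp:
            design_path = Path(tmp) / "design.csv"
            out_path = Path(tmp) / "fit.json"
            self.design.to_csv(design_path, index=False)
            with resources.as_file(script) as sp:
                proc = subprocess.run(
                    [exe, str(sp), str(design_path), str(out_path)],
                    capture_output=True, text=True)
            if proc.returncode != 0 or not out_path.exists():
                raise ConvergenceError(
                    f"glmer fit failed:\n{proc.stderr[-2000:]}")
            result = json.loads(out_path.read_text())
        return EverSmokingResults(self, result)


class EverSmokingResults:
    """Fitted ever-smoking model: fixed effects, (co)variances, summary."""

    def __init__(self, model: EverSmokingModel, raw: dict):
        self.model = model
        self.raw = raw
        self.converged = bool(raw["converged"])
        self.llf = float(raw["loglik"])
        names = [_R_NAME_MAP.get(n, n) for n in raw["fixed"]["names"]]
        self.fe_params = pd.Series(raw["fixed"]["estimate"], index=names,
                                   dtype=float)
        self.bse = pd.Series(raw["fixed"]["se"], index=names, dtype=float)
        self.random = {k: float(v) for k, v in raw["random"].items()}

    @property
    def params(self) -> SmokingModelParams:
        fixed = {k: float(v) for k, v in self.fe_params.items()
                 if k != "intercept"}
        ses = {k: float(v) for k, v in self.bse.items()}
        r = self.random
        return SmokingModelParams(
            intercept=float(self.fe_params["intercept"]), fixed_coefs=fixed,
            var_state=r["var_state"],
            var_state_black_slope=r["var_state_black_slope"],
            cov_state_blackslope=r["cov_state_blackslope"],
            var_cbsa=r["var_cbsa"], var_household=r["var_household"],
            ses=ses, llf=self.llf)

    def summary(self) -> str:
        lines = ["Multilevel logistic ever-smoking model (Laplace/glmer)",
                 f"observations: {len(self.model.data)}   "
                 f"log-likelihood: {self.llf:.2f}   "
                 f"converged: {self.converged}", "",
                 f"{'term':<30}{'estimate':>10}{'se':>9}{'OR':>8}"]
        for name in self.fe_params.index:
            est = self.fe_params[name]
            lines.append(f"{name:<30}{est:>10.4f}{self.bse[name]:>9.4f}"
                         f"{math.exp(est):>8.3f}")
        lines.append("")
        for k, v in self.random.items():
            lines.append(f"{k}: {v:.4f}")
        return "\n".join(lines)
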