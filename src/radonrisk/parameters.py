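"""Model parameter bundles and the packaged coefficient tables.

The risk chain is parameter-driven: three regression models (log-linear radon
concentration, multinomial house type, multilevel logistic ever-smoking) are
consumed through their coefficient bundles.  The published point estimates
ship with the package as long-format CSV tables so users can substitute
refitted parameters; :func:`load_coefficients` reads either a packaged table
name (``"radon"``, ``"housing"``, ``"smoking"``) or a path.

House-type association strengths are published as odds ratios only, so the
packaged housing table stores the printed ORs (``scale=or``) and the loader
converts them to log-odds via the natural log; the model intercepts are
printed on the log-odds scale and stored as-is (``scale=logit``).  Reference
categories carry coefficient exactly 0 and are materialised by the loader,
not stored.

The radon model's level variance components were not published; the packaged
values (state 0.05, PSU 0.10, SSU 0.10, residual 1.00 on the log scale) are
package assumptions used only by the synthetic-data generator, documented in
docs/methods.md.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocab
from .exceptions import SchemaError, ValidationError

_PACKAGED = {
    "radon": "radon_coefs.csv",
    "housing": "housing_coefs.csv",
    "smoking": "smoking_coefs.csv",
}


@dataclass
class RadonModelParams:
    """Fixed effects and level variances of the log-linear radon model.

    All coefficients are on the log(pCi/L) scale.  Reference levels
    (Midwest region, Low geological potential, detached-with-basement
    house type) carry coefficient 0.
    """

    intercept: float
    region_coefs: dict
    geo_coefs: dict
    hdd_coef: float
    diurnal_coef: float
    housetype_coefs: dict
    variance_components: dict = field(default_factory=dict)
    ses: dict = field(default_factory=dict)
    llf: float | None = None

    def __post_init__(self) -> None:
        self.region_coefs.setdefault(vocab.RADON_REGION_REF, 0.0)
        self.geo_coefs.setdefault(vocab.GEO_REF, 0.0)
        self.housetype_coefs.setdefault(vocab.HOUSE_TYPE_REF, 0.0)
        if self.region_coefs[vocab.RADON_REGION_REF] != 0.0:
            raise ValidationError("reference region must carry coefficient 0")
        if any(v < 0 for v in self.variance_components.values()):
            raise ValidationError("variance components must be >= 0")


@dataclass
class HousingModelParams:
    """Intercepts and log-odds of the multinomial house-type model.

    ``coefs`` maps ``(outcome, term, level)`` to the natural log of the
    published odds ratio; the reference outcome (detached with basement)
    has an identically zero linear predictor.
    """

    intercepts: dict
    coefs: dict
    ses: dict = field(default_factory=dict)
    llf: float | None = None
    outcomes: tuple = vocab.HOUSE_TYPE_OUTCOMES
    reference: str = vocab.HOUSE_TYPE_REF

    def odds_ratio(self, outcome: str, term: str, level: str) -> float:
        return math.exp(self.coefs[(outcome, term, level)])


@dataclass
class SmokingModelParams:
    """Fixed effects and random-parameter (co)variances of the ever-smoking model.

    Fixed effects are logits; ``fixed_coefs`` keys are ``"male"``,
    ``"age:<level>"``, ``"poverty:below"``, ``"income_not_reported"``,
    ``"race:<level>"``, ``"race_male:<level>"``, ``"state_tax"``,
    ``"prev_state_prevalence"``, ``"indoor_restrictions"``,
    ``"cbsa_poverty_above_median"``, ``"cbsa_nonmetropolitan"``.
    """

    intercept: float
    fixed_coefs: dict
    var_state: float
    var_state_black_slope: float
    cov_state_blackslope: float
    var_cbsa: float
    var_household: float
    ses: dict = field(default_factory=dict)
    llf: float | None = None

    def __post_init__(self) -> None:
        for name in ("var_state", "var_state_black_slope", "var_cbsa",
                     "var_household"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        bound = math.sqrt(self.var_state * self.var_state_black_slope)
        if abs(self.cov_state_blackslope) > bound + 1e-12:
            raise ValidationError(
                "covariance of state intercept and black slope violates "
                "Cauchy-Schwarz against the stated variances"
            )


@dataclass(frozen=True)
class ExposureConstants:
    """Physical constants converting radon concentration to cumulative exposure.

    The derived rate ``wl_per_pci * wlm_per_wl_year * occupancy_fraction``
    is about 0.144 WLM per year per pCi/L under the defaults.
    ``equilibrium_fraction`` is documentation only: it is already embodied
    in ``wl_per_pci``.
    """

    wl_per_pci: float = 0.004
    wlm_per_wl_year: float = 51.6
    occupancy_fraction: float = 0.70
    equilibrium_fraction: float = 0.40
    exposure_duration_years: float = 75.0

    def __post_init__(self) -> None:
        for name in ("wl_per_pci", "wlm_per_wl_year", "occupancy_fraction",
                     "equilibrium_fraction", "exposure_duration_years"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.occupancy_fraction > 1:
            raise ValidationError("occupancy_fraction must be in (0, 1]")


@dataclass(frozen=True)
class UnitRiskFactors:
    """Lifetime fatal lung-cancer risk per WLM by sex and smoking status."""

    male_ever: float = 0.00106
    female_ever: float = 0.000851
    male_never: float = 0.000174
    female_never: float = 0.000161
    general_population: float = 0.00054

    def __post_init__(self) -> None:
        for name in ("male_ever", "female_ever", "male_never", "female_never",
                     "general_population"):
            v = getattr(self, name)
            if not 0 < v < 0.01:
                raise ValidationError(f"{name} out of plausible range: {v}")
        if self.male_ever <= self.male_never or self.female_ever <= self.female_never:
            raise ValidationError(
                "ever-smoker unit risk must exceed never-smoker unit risk"
            )

    def lookup(self, sex: str, smoking: str) -> float:
        if sex not in vocab.SEXES:
            raise ValidationError(f"unknown sex {sex!r}")
        if smoking not in ("ever", "never"):
            raise ValidationError(f"unknown smoking status {smoking!r}")
        return getattr(self, f"{sex}_{smoking}")


def _read_table(source) -> pd.DataFrame:
    if isinstance(source, str) and source in _PACKAGED:
        ref = resources.files("radonrisk.data") / _PACKAGED[source]
        with resources.as_file(ref) as path:
            df = pd.read_csv(path, dtype={"term": str, "level": str})
    else:
        path = Path(source)
        if not path.exists():
            raise SchemaError(f"coefficient table not found: {source}")
        df = pd.read_csv(path, dtype={"term": str, "level": str})
    required = {"term", "level", "estimate", "scale"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"coefficient table missing columns: {sorted(missing)}")
    num = pd.to_numeric(df["estimate"], errors="coerce")
    bad = ~np.isfinite(num.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        raise SchemaError(
            f"non-numeric estimate at row index {int(np.flatnonzero(bad)[0])}"
        )
    df["estimate"] = num
    df["level"] = df["level"].fillna("")
    return df


def _pick(df: pd.DataFrame, term: str, level: str = "") -> tuple[float, float]:
    rows = df[(df["term"] == term) & (df["level"] == level)]
    if len(rows) != 1:
        raise SchemaError(
            f"expected exactly one row for term={term!r} level={level!r}, "
            f"found {len(rows)}"
        )
    est = float(rows["estimate"].iloc[0])
    se = rows["se"].iloc[0] if "se" in rows else float("nan")
    return est, float(se) if pd.notna(se) else float("nan")


def _load_radon(df: pd.DataFrame) -> RadonModelParams:
    intercept, se0 = _pick(df, "intercept")
    ses = {"intercept": se0}
    region, geo, ht = {}, {}, {}
    for lvl in vocab.REGIONS:
        if lvl == vocab.RADON_REGION_REF:
            continue
        region[lvl], ses[f"region:{lvl}"] = _pick(df, "region", lvl)
    for lvl in ("Medium", "High"):
        geo[lvl], ses[f"geo_potential:{lvl}"] = _pick(df, "geo_potential", lvl)
    hdd, ses["hdd"] = _pick(df, "hdd")
    diurnal, ses["diurnal_swing"] = _pick(df, "diurnal_swing")
    for lvl in vocab.HOUSE_TYPE_OUTCOMES:
        ht[lvl], ses[f"house_type:{lvl}"] = _pick(df, "house_type", lvl)
    vc = {}
    for lvl in ("state", "psu", "ssu", "residual"):
        vrows = df[(df["term"] == "variance") & (df["level"] == lvl)]
        if len(vrows) == 1:
            vc[lvl] = float(vrows["estimate"].iloc[0])
    return RadonModelParams(
        intercept=intercept, region_coefs=region, geo_coefs=geo,
        hdd_coef=hdd, diurnal_coef=diurnal, housetype_coefs=ht,
        variance_components=vc, ses=ses,
    )


def _load_housing(df: pd.DataFrame) -> HousingModelParams:
    if "outcome" not in df.columns:
        raise SchemaError("housing coefficient table requires an 'outcome' column")
    intercepts, coefs, ses = {}, {}, {}
    for out in vocab.HOUSE_TYPE_OUTCOMES:
        rows = df[(df["term"] == "intercept") & (df["outcome"] == out)]
        if len(rows) != 1:
            raise SchemaError(f"missing intercept for outcome {out!r}")
        intercepts[out] = float(rows["estimate"].iloc[0])
        ses[(out, "intercept", "")] = float(rows["se"].iloc[0])
    terms = {
        "poverty": ("below",),
        "sex": ("male",),
        "race": ("black", "asian", "other", "native"),
        "region": ("Northeast", "Midwest", "West"),
        "age": ("<18", "18-24", "25-34", "35-44", "55-64", "65-74", "75+"),
    }
    for term, levels in terms.items():
        for lvl in levels:
            for out in vocab.HOUSE_TYPE_OUTCOMES:
                rows = df[(df["term"] == term) & (df["level"] == lvl)
                          & (df["outcome"] == out)]
                if len(rows) != 1:
                    raise SchemaError(
                        f"expected exactly one row for term={term!r} "
                        f"level={lvl!r} outcome={out!r}, found {len(rows)}"
                    )
                est = float(rows["estimate"].iloc[0])
                scale = rows["scale"].iloc[0]
                if scale == "or":
                    if est <= 0:
                        raise SchemaError(f"odds ratio must be positive, got {est}")
                    est = math.log(est)
                coefs[(out, term, lvl)] = est
                se = rows["se"].iloc[0]
                if pd.notna(se):
                    ses[(out, term, lvl)] = float(se)
    return HousingModelParams(intercepts=intercepts, coefs=coefs, ses=ses)


_SMOKING_SCALARS = ("male", "income_not_reported", "state_tax",
                    "prev_state_prevalence", "indoor_restrictions",
                    "cbsa_poverty_above_median", "cbsa_nonmetropolitan")


def _load_smoking(df: pd.DataFrame) -> SmokingModelParams:
    intercept, se0 = _pick(df, "intercept")
    fixed, ses = {}, {"intercept": se0}
    for term in _SMOKING_SCALARS:
        fixed[term], ses[term] = _pick(df, term)
    for lvl in vocab.AGE_GROUPS:
        if lvl == vocab.AGE_REF:
            continue
        fixed[f"age:{lvl}"], ses[f"age:{lvl}"] = _pick(df, "age", lvl)
    fixed["poverty:below"], ses["poverty:below"] = _pick(df, "poverty", "below")
    for lvl in vocab.RACES:
        if lvl == vocab.RACE_REF:
            continue
        fixed[f"race:{lvl}"], ses[f"race:{lvl}"] = _pick(df, "race", lvl)
        fixed[f"race_male:{lvl}"], ses[f"race_male:{lvl}"] = _pick(
            df, "race_male", lvl)
    var = {}
    for lvl in ("state", "state_black_slope", "cbsa", "household"):
        var[lvl], _ = _pick(df[df["term"] == "variance"], "variance", lvl)
    cov, _ = _pick(df, "covariance", "state_black_slope")
    return SmokingModelParams(
        intercept=intercept, fixed_coefs=fixed,
        var_state=var["state"], var_state_black_slope=var["state_black_slope"],
        cov_state_blackslope=cov, var_cbsa=var["cbsa"],
        var_household=var["household"], ses=ses,
    )


def load_coefficients(source):
    """Load a model parameter bundle from a packaged table name or a path.

    Parameters
    ----------
    source : str or path-like
        One of ``"radon"``, ``"housing"``, ``"smoking"``, or a path to a
        CSV file in the same long format (columns ``term, level[, outcome],
        estimate, se, scale``).  The kind of bundle is inferred from the
        terms present.

    Returns
    -------
    RadonModelParams, HousingModelParams or SmokingModelParams
    """
    df = _read_table(source)
    if "outcome" in df.columns and df["outcome"].notna().any():
        return _load_housing(df)
    terms = set(df["term"])
    if "house_type" in terms or "geo_potential" in terms:
        return _load_radon(df)
    if "race_male" in terms or "state_tax" in terms:
        return _load_smoking(df)
    raise SchemaError(
        "could not infer table kind: expected radon, housing or smoking terms"
    )


def load_constants(path=None) -> tuple[ExposureConstants, UnitRiskFactors]:
    """Load exposure constants and unit risk factors.

    With no argument, reads the packaged ``risk_constants.toml``.  A user
    TOML file may override any subset of keys; unspecified keys keep their
    packaged defaults.
    """
    ref = resources.files("radonrisk.data") / "risk_constants.toml"
    with resources.as_file(ref) as p:
        packaged = tomllib.loads(Path(p).read_text())
    exposure = dict(packaged["exposure"])
    unit = dict(packaged["unit_risk"])
    if path is not None:
        user = tomllib.loads(Path(path).read_text())
        exposure.update(user.get("exposure", {}))
        unit.update(user.get("unit_risk", {}))
    return (
        ExposureConstants(**exposure),
        UnitRiskFactors(**unit),
    )
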