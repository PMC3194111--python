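"""Core record types: demographic bins, county context, per-bin risk results.

A :class:`DemographicBin` is the atomic unit of prediction and aggregation:
one county x age x sex x race x poverty cell with an adult population count.
A :class:`CountyContext` carries everything geographic that a bin inherits
(census region, geological radon potential, meteorology, model residuals and
state tobacco-policy covariates).  Residual fields default to zero, which is
exactly the treatment of states and metro areas absent from the underlying
survey samples: their predictions fall back to fixed effects only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import vocab
from .exceptions import ValidationError


def _check_level(value: str, allowed, what: str) -> None:
    if value not in allowed:
        raise ValidationError(
            f"unknown {what} {value!r}; expected one of {sorted(allowed)}"
        )


@dataclass(frozen=True)
class DemographicBin:
    """One county x age x sex x race x poverty cell with a population count."""

    county_id: str
    state_id: str
    age_group: str
    sex: str
    race: str
    poverty: str
    count: int = 0

    def __post_init__(self) -> None:
        _check_level(self.age_group, vocab.AGE_GROUPS, "age_group")
        _check_level(self.sex, vocab.SEXES, "sex")
        _check_level(self.race, vocab.RACES, "race")
        _check_level(self.poverty, vocab.POVERTY, "poverty")
        if self.count < 0:
            raise ValidationError(f"count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class CountyContext:
    """Geographic context of a county, inherited by each of its bins.

    ``radon_*`` residuals are on the log-concentration scale; ``smoking_*``
    residuals on the logit scale.  Counties/states/CBSAs without estimated
    residuals keep the zero defaults.
    """

    county_id: str
    state_id: str
    region: str
    geo_potential: str
    heating_infiltration_degree_days: float
    avg_diurnal_swing: float
    radon_state_residual: float = 0.0
    radon_county_residual: float = 0.0
    smoking_state_residual: float = 0.0
    smoking_state_black_slope: float = 0.0
    smoking_cbsa_residual: float = 0.0
    state_cigarette_tax: float = 0.0
    prev_state_prevalence_2003: float = 0.0
    indoor_restriction_flag: int = 0
    cbsa_poverty_above_median: int = 0
    cbsa_nonmetropolitan: int = 0

    def __post_init__(self) -> None:
        _check_level(self.region, vocab.REGIONS, "region")
        _check_level(self.geo_potential, vocab.GEO_POTENTIAL, "geo_potential")
        if self.heating_infiltration_degree_days < 0:
            raise ValidationError("heating_infiltration_degree_days must be >= 0")
        for name in ("radon_state_residual", "radon_county_residual",
                     "smoking_state_residual", "smoking_state_black_slope",
                     "smoking_cbsa_residual", "state_cigarette_tax",
                     "prev_state_prevalence_2003", "avg_diurnal_swing"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        for name in ("indoor_restriction_flag", "cbsa_poverty_above_median",
                     "cbsa_nonmetropolitan"):
            if getattr(self, name) not in (0, 1):
                raise ValidationError(f"{name} must be 0 or 1")


@dataclass(frozen=True)
class BinRiskResult:
    """Per-bin output of the three-model prediction chain and risk formula."""

    bin: DemographicBin
    p_ever_smoking: float
    housetype_probs: dict = field(default_factory=dict)
    concentration_by_type: dict = field(default_factory=dict)
    expected_concentration: float = 0.0
    lifetime_risk: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_ever_smoking <= 1.0:
            raise ValidationError("p_ever_smoking must be in [0, 1]")
        if self.housetype_probs:
            total = sum(self.housetype_probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"housetype_probs must sum to 1 (got {total!r})"
                )
            if any(p < 0 or p > 1 for p in self.housetype_probs.values()):
                raise ValidationError("house-type probabilities must be in [0, 1]")
        if not 0.0 <= self.lifetime_risk < 1.0:
            raise ValidationError("lifetime_risk must be in [0, 1)")
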