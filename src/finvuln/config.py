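"""Run configuration: covariate sets, basic living cost, strata, copula candidates.

The measure needs a handful of global choices — which covariates enter the
income and medical-expenditure equations, the subsistence floor (basic living
cost, BLC), which survey waves and strata exist, and numerical guards such as
the variance floor.  ``RunConfig`` collects them with defaults matching the
CHARLS application of the measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

#: Covariates of the income equation (household-head demographics plus
#: disability and health shock).
INCOME_COVARIATES: tuple[str, ...] = (
    "age", "gender", "education", "married", "size", "labor", "area",
    "disable", "health_s",
)

#: Covariates of the medical-expenditure equation: income covariates plus
#: health status, chronic disease, and the three medical-insurance indicators.
MEDICAL_COVARIATES: tuple[str, ...] = INCOME_COVARIATES + (
    "health", "diseases", "insur_em", "insur_cm", "insur_om",
)

#: All determinants entering the vulnerability panel regressions.
DETERMINANTS: tuple[str, ...] = (
    "age", "gender", "education", "married", "size", "labor", "area",
    "health", "diseases", "disable", "health_s",
    "insur_em", "insur_cm", "insur_om",
)

BINARY_COLUMNS: tuple[str, ...] = (
    "gender", "married", "area", "diseases", "disable", "health_s",
    "insur_em", "insur_cm", "insur_om",
)

MONETARY_COLUMNS: tuple[str, ...] = ("i", "me", "dp", "la")

COPULA_FAMILIES: tuple[str, ...] = (
    "gaussian", "clayton", "gumbel", "frank", "independence",
)


def default_blc(usd_cny_rate: float) -> float:
    """Annual per-capita basic living cost from the USD 2/day poverty line.

    Parameters
    ----------
    usd_cny_rate : float
        CNY per USD exchange rate; must be positive.

    Returns
    -------
    float
        ``2 * 365 * usd_cny_rate`` in CNY per person per year.
    """
    if usd_cny_rate <= 0:
        raise ValueError(f"exchange rate must be positive, got {usd_cny_rate}")
    return 2.0 * 365.0 * usd_cny_rate


@dataclass
class RunConfig:
    """Global settings for a vulnerability-measurement run.

    ``blc_per_capita`` defaults to the USD 2/day/person international
    poverty line converted at ``usd_cny_rate``.
    """

    usd_cny_rate: float = 6.5
    blc_per_capita: float | None = None
    waves: tuple[int, ...] = (2011, 2013, 2015)
    strata: tuple[str, ...] = ("urban", "rural")
    covariates_income: tuple[str, ...] = INCOME_COVARIATES
    covariates_medical: tuple[str, ...] = MEDICAL_COVARIATES
    seed: int = 0
    variance_floor: float = 1e-4
    copula_candidates: tuple[str, ...] = ("gaussian", "clayton", "gumbel", "frank")
    gof_bootstrap_reps: int = 200
    clean_policy: str = "drop"
    me_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.blc_per_capita is None:
            self.blc_per_capita = default_blc(self.usd_cny_rate)
        if self.blc_per_capita <= 0:
            raise ValueError("blc_per_capita must be positive")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")
        for fam in self.copula_candidates:
            if fam not in COPULA_FAMILIES:
                raise ValueError(f"unknown copula family {fam!r}")
        if self.clean_policy not in ("drop", "offset"):
            raise ValueError("clean_policy must be 'drop' or 'offset'")
        self.waves = tuple(int(w) for w in self.waves)
        self.covariates_income = tuple(c.lower() for c in self.covariates_income)
        self.covariates_medical = tuple(c.lower() for c in self.covariates_medical)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
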