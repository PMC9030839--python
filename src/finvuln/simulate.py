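"""Synthetic household panels with the exact structure the measure assumes.

The generator draws covariates calibrated to the published CHARLS descriptive
statistics (urban and rural strata), then produces income and medical
expenditure from the generative model itself: log-normal margins with
covariate-linear mean and variance, coupled through a chosen copula.  Debt
payments and liquid assets are zero-inflated log-normal, moment-matched to
the published means.  Every panel comes with a ground-truth sidecar holding
the generative coefficients and each household's true vulnerability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .config import INCOME_COVARIATES, MEDICAL_COVARIATES, default_blc
from .copula import CopulaModel, copula_rvs, _check_gamma
from .marginals import MarginalModel


def coef_vector(coefs: dict, covariate_names) -> np.ndarray:
    """(intercept, covariates...) vector from a named coefficient dict."""
    return np.array([coefs.get("const", 0.0)]
                    + [coefs.get(c, 0.0) for c in covariate_names])


@dataclass
class ZeroInflatedLogNormal:
    """Point mass at zero plus a log-normal positive part."""

    p_positive: float
    meanlog: float
    sdlog: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        positive = rng.uniform(size=n) < self.p_positive
        values = np.where(positive, rng.lognormal(self.meanlog, self.sdlog, size=n), 0.0)
        return values


@dataclass
class CovariateModel:
    """Marginal distributions of the household covariates (base wave).

    Continuous/count covariates use simple parametric families whose
    parameters are set to the published stratum means and dispersions;
    binary covariates are Bernoulli at the published shares.
    """

    age_mean: float = 61.3
    age_sd: float = 10.1
    age_range: tuple[float, float] = (29, 103)
    p_gender: float = 0.80
    education_mean: float = 6.4
    education_sd: float = 4.2
    p_married: float = 0.80
    size_rate: float = 2.9          # household size = 1 + Poisson(size_rate)
    labor_mean: float = 0.39
    labor_sd: float = 0.30
    p_area: float = 0.31
    health_probs: tuple[float, ...] = (0.01, 0.04, 0.22, 0.45, 0.23, 0.05)
    p_diseases: float = 0.86
    p_disable: float = 0.23
    p_health_s: float = 0.30
    p_insur_em: float = 0.19
    p_insur_cm: float = 0.04
    p_insur_om: float = 0.79

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        lo, hi = self.age_range
        a, b = (lo - self.age_mean) / self.age_sd, (hi - self.age_mean) / self.age_sd
        age = np.round(stats.truncnorm.rvs(a, b, loc=self.age_mean, scale=self.age_sd,
                                           size=n, random_state=rng))
        education = np.clip(np.round(rng.normal(self.education_mean,
                                                self.education_sd, n)), 0, 19)
        size = 1 + np.minimum(rng.poisson(self.size_rate, n), 17)
        m, v = self.labor_mean, self.labor_sd**2
        common = m * (1 - m) / v - 1.0
        labor = rng.beta(m * common, (1 - m) * common, n)
        health = 1 + rng.choice(6, size=n, p=np.asarray(self.health_probs))

        def bern(p):
            return (rng.uniform(size=n) < p).astype(int)

        return pd.DataFrame({
            "age": age, "gender": bern(self.p_gender), "education": education,
            "married": bern(self.p_married), "size": size, "labor": labor,
            "area": bern(self.p_area), "health": health,
            "diseases": bern(self.p_diseases), "disable": bern(self.p_disable),
            "health_s": bern(self.p_health_s), "insur_em": bern(self.p_insur_em),
            "insur_cm": bern(self.p_insur_cm), "insur_om": bern(self.p_insur_om),
        })

    def evolve(self, df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        """Advance the covariates by one two-year wave.

        Heads age by two years; household size, labor share and health take
        small random steps; absorbing states (chronic disease, disability)
        can switch on; insurance take-up can switch on; the health-shock
        indicator is redrawn each wave.  Gender, area, and education are
        held fixed.
        """
        n = len(df)
        out = df.copy()
        out["age"] = df["age"] + 2
        step = rng.choice([-1, 0, 1], size=n, p=[0.08, 0.84, 0.08])
        out["size"] = np.clip(df["size"] + step, 1, 18)
        out["labor"] = np.clip(df["labor"] + rng.normal(0, 0.06, n), 0.0, 1.0)
        hstep = rng.choice([-1, 0, 1], size=n, p=[0.12, 0.73, 0.15])
        out["health"] = np.clip(df["health"] + hstep, 1, 6)
        out["married"] = np.where((df["married"] == 1) & (rng.uniform(size=n) < 0.03),
                                  0, df["married"])
        for col, p_on in (("diseases", 0.04), ("disable", 0.02),
                          ("insur_em", 0.04), ("insur_cm", 0.01), ("insur_om", 0.05)):
            switch_on = (df[col] == 0) & (rng.uniform(size=n) < p_on)
            out[col] = np.where(switch_on, 1, df[col])
        out["health_s"] = (rng.uniform(size=n) < self.p_health_s).astype(int)
        return out


@dataclass
class SyntheticSpec:
    """Ground-truth parameters of a synthetic panel.

    ``alpha``/``theta`` are the income mean/variance coefficient dicts over
    ``income_covariates``; ``beta``/``omega`` likewise for medical
    expenditure over ``medical_covariates``.  ``gamma`` is the copula
    dependence parameter.
    """

    n_households: int
    alpha: dict
    beta: dict
    theta: dict
    omega: dict
    copula_family: str = "gaussian"
    gamma: float | None = 0.144
    waves: tuple[int, ...] = (2011, 2013, 2015)
    stratum: str = "urban"
    covariates: CovariateModel = field(default_factory=CovariateModel)
    dp_model: ZeroInflatedLogNormal = field(
        default_factory=lambda: ZeroInflatedLogNormal(0.10, 6.2, 1.2))
    la_model: ZeroInflatedLogNormal = field(
        default_factory=lambda: ZeroInflatedLogNormal(0.85, 7.63, 1.5))
    blc_per_capita: float = default_blc(6.5)
    income_covariates: tuple[str, ...] = INCOME_COVARIATES
    medical_covariates: tuple[str, ...] = MEDICAL_COVARIATES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_households < 1:
            raise ValueError("n_households must be >= 1")
        if self.copula_family != "independence":
            _check_gamma(self.copula_family, self.gamma)

    def alpha_vec(self):
        return coef_vector(self.alpha, self.income_covariates)

    def beta_vec(self):
        return coef_vector(self.beta, self.medical_covariates)

    def theta_vec(self):
        return coef_vector(self.theta, self.income_covariates)

    def omega_vec(self):
        return coef_vector(self.omega, self.medical_covariates)

    def true_marginal_models(self) -> tuple[MarginalModel, MarginalModel]:
        income = MarginalModel("income", list(self.income_covariates),
                               self.alpha_vec(), self.theta_vec(), self.n_households)
        medical = MarginalModel("medical", list(self.medical_covariates),
                                self.beta_vec(), self.omega_vec(), self.n_households)
        return income, medical

    def true_copula_model(self) -> CopulaModel:
        return CopulaModel(self.copula_family, self.gamma, np.nan, self.n_households)


# ---------------------------------------------------------------------------
# default stratum calibrations

_URBAN_ALPHA = {"const": 7.78, "age": 0.004, "gender": 0.10, "education": 0.045,
                "married": 0.06, "size": -0.04, "labor": 0.8, "area": 0.3,
                "disable": -0.25, "health_s": -0.12}
_URBAN_THETA = {"const": 0.75, "education": -0.015, "size": 0.02, "labor": 0.35,
                "disable": 0.3, "health_s": 0.25}
_URBAN_BETA = {"const": 4.0, "age": 0.01, "gender": -0.05, "education": 0.01,
               "married": 0.05, "size": -0.03, "labor": -0.3, "area": 0.1,
               "disable": 0.35, "health_s": 0.9, "health": 0.25,
               "diseases": 0.3, "insur_em": 0.1, "insur_cm": 0.05,
               "insur_om": 0.05}
_URBAN_OMEGA = {"const": 1.55, "education": -0.01, "size": 0.02, "labor": -0.3,
                "disable": 0.2, "health_s": 0.3, "health": 0.15,
                "diseases": 0.15}


def urban_spec(n_households: int = 2000, seed: int = 0, **overrides) -> SyntheticSpec:
    """Default urban-stratum generative spec (Gaussian copula, gamma = 0.144)."""
    spec = SyntheticSpec(
        n_households=n_households,
        alpha=dict(_URBAN_ALPHA), theta=dict(_URBAN_THETA),
        beta=dict(_URBAN_BETA), omega=dict(_URBAN_OMEGA),
        copula_family="gaussian", gamma=0.144, stratum="urban", seed=seed)
    return replace(spec, **overrides) if overrides else spec


def rural_spec(n_households: int = 2000, seed: int = 0, **overrides) -> SyntheticSpec:
    """Default rural-stratum spec (gamma = 0.214, lower income level)."""
    alpha = dict(_URBAN_ALPHA)
    alpha["const"] = 7.54
    cov = CovariateModel(
        age_mean=61.9, age_sd=9.9, age_range=(19, 102), p_gender=0.81,
        education_mean=5.4, education_sd=4.0, p_married=0.79, size_rate=2.88,
        labor_mean=0.37, labor_sd=0.30, p_area=0.27,
        health_probs=(0.01, 0.04, 0.20, 0.44, 0.26, 0.05), p_diseases=0.89,
        p_disable=0.25, p_health_s=0.29, p_insur_em=0.11, p_insur_cm=0.03,
        p_insur_om=0.86)
    spec = SyntheticSpec(
        n_households=n_households,
        alpha=alpha, theta=dict(_URBAN_THETA),
        beta=dict(_URBAN_BETA), omega=dict(_URBAN_OMEGA),
        copula_family="gaussian", gamma=0.214, stratum="rural",
        covariates=cov,
        dp_model=ZeroInflatedLogNormal(0.08, 6.0, 1.2),
        la_model=ZeroInflatedLogNormal(0.82, 7.26, 1.5),
        seed=seed)
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# generation

def _check_positive_variance(spec: SyntheticSpec, cov: pd.DataFrame) -> None:
    from .marginals import _design

    for name, vec, cols in (("theta", spec.theta_vec(), spec.income_covariates),
                            ("omega", spec.omega_vec(), spec.medical_covariates)):
        pred = _design(cov, cols) @ vec
        if np.any(pred <= 0):
            raise ValueError(
                f"{name} variance model non-positive for {int(np.sum(pred <= 0))} "
                "generated covariate vector(s); spec rejected")


def generate_covariates(spec: SyntheticSpec, rng=None) -> pd.DataFrame:
    """Base-wave covariate table (n_households rows)."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    cov = spec.covariates.sample(spec.n_households, rng)
    _check_positive_variance(spec, cov)
    return cov


def generate_outcomes(spec: SyntheticSpec, covariates: pd.DataFrame,
                      rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw (I, ME) on the natural scale from the generative model."""
    from .marginals import _design

    rng = np.random.default_rng(spec.seed if rng is None else rng)
    _check_positive_variance(spec, covariates)
    n = len(covariates)
    uv = copula_rvs(spec.copula_family, spec.gamma, n, rng)
    Xi = _design(covariates, spec.income_covariates)
    Yi = _design(covariates, spec.medical_covariates)
    ln_i = Xi @ spec.alpha_vec() + np.sqrt(Xi @ spec.theta_vec()) * stats.norm.ppf(uv[:, 0])
    ln_me = Yi @ spec.beta_vec() + np.sqrt(Yi @ spec.omega_vec()) * stats.norm.ppf(uv[:, 1])
    return np.exp(ln_i), np.exp(ln_me)


def generate_panel(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict]:
    """Full multi-wave panel plus the ground-truth sidecar.

    The sidecar holds the generative coefficient dicts, the copula family
    and gamma, and each row's true vulnerability ``delta_true`` computed
    from the generative parameters themselves.
    """
    from .vulnerability import distress_probability

    rng = np.random.default_rng(spec.seed)
    frames = []
    cov = spec.covariates.sample(spec.n_households, rng)
    _check_positive_variance(spec, cov)
    ids = [f"{spec.stratum[0]}{k:06d}" for k in range(spec.n_households)]
    for w, wave in enumerate(spec.waves):
        if w > 0:
            cov = spec.covariates.evolve(cov, rng)
            _check_positive_variance(spec, cov)
        i_vals, me_vals = generate_outcomes(spec, cov, rng)
        frame = cov.copy()
        frame.insert(0, "household_id", ids)
        frame.insert(1, "wave", wave)
        frame.insert(2, "stratum", spec.stratum)
        frame.insert(3, "i", i_vals)
        frame.insert(4, "me", me_vals)
        frame.insert(5, "dp", spec.dp_model.sample(spec.n_households, rng))
        frame.insert(6, "la", spec.la_model.sample(spec.n_households, rng))
        frames.append(frame)
    panel = pd.concat(frames, ignore_index=True)

    income_m, medical_m = spec.true_marginal_models()
    scored = distress_probability(income_m, medical_m, spec.true_copula_model(),
                                  panel, spec.blc_per_capita)
    truth = {
        "alpha": dict(spec.alpha), "beta": dict(spec.beta),
        "theta": dict(spec.theta), "omega": dict(spec.omega),
        "copula_family": spec.copula_family, "gamma": spec.gamma,
        "blc_per_capita": spec.blc_per_capita,
        "delta_true": scored["delta"].to_numpy(),
    }
    return panel, truth
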