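"""Copula dependence between income and medical-expenditure shocks.

By Sklar's theorem the joint distribution of (ln I, ln ME) factors into the
two conditional-normal margins and a copula C(u, v; gamma).  This module
builds the pseudo-observations (u_i, v_i) from fitted margins, estimates the
dependence parameter gamma by maximum likelihood with the margins held fixed
(inference-functions-for-margins), and selects a family by an
empirical-copula Cramer-von Mises goodness-of-fit test with parametric
bootstrap.

Family CDFs/densities/samplers come from ``statsmodels.distributions.copula``;
the estimation, testing, and selection logic lives here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, stats
from statsmodels.distributions.copula.api import (
    ClaytonCopula,
    FrankCopula,
    GaussianCopula,
    GumbelCopula,
    IndependenceCopula,
)

CLIP_EPS = 1e-10

# family -> (constructor, admissible open interval for gamma, MLE search bounds)
_FAMILIES = {
    "gaussian": (lambda g: GaussianCopula(corr=g), (-1.0, 1.0), (-0.999, 0.999)),
    "clayton": (lambda g: ClaytonCopula(theta=g), (0.0, np.inf), (1e-3, 30.0)),
    "gumbel": (lambda g: GumbelCopula(theta=g), (1.0, np.inf), (1.0 + 1e-9, 30.0)),
    "frank": (lambda g: FrankCopula(theta=g), (-np.inf, np.inf), (-35.0, 35.0)),
    "independence": (lambda g: IndependenceCopula(), (None, None), None),
}


def _check_gamma(family: str, gamma) -> None:
    if family not in _FAMILIES:
        raise ValueError(f"unknown copula family {family!r}")
    if family == "independence":
        return
    lo, hi = _FAMILIES[family][1]
    ok = lo < gamma < hi
    if family == "gumbel":
        ok = gamma >= 1.0
    if family == "frank":
        ok = gamma != 0.0
    if not ok:
        raise ValueError(f"gamma={gamma} outside admissible range for {family}")


def _make(family: str, gamma):
    _check_gamma(family, gamma)
    return _FAMILIES[family][0](gamma)


def copula_cdf(family: str, gamma, u, v):
    """C(u, v; gamma) — joint probability of {U <= u, V <= v}.

    ``u`` and ``v`` may be scalars or arrays; uniform-margin boundary cases
    (u or v in {0, 1}) are handled exactly.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((u < 0) | (u > 1)) or np.any((v < 0) | (v > 1)):
        raise ValueError("u and v must lie in [0, 1]")
    if family == "independence":
        return u * v
    cop = _make(family, gamma)
    scalar = (np.broadcast(u, v).shape == ())
    u_b, v_b = np.broadcast_arrays(np.atleast_1d(u), np.atleast_1d(v))
    uu = np.clip(u_b, CLIP_EPS, 1 - CLIP_EPS)
    vv = np.clip(v_b, CLIP_EPS, 1 - CLIP_EPS)
    out = np.asarray(cop.cdf(np.column_stack([uu.ravel(), vv.ravel()])),
                     dtype=float).reshape(u_b.shape)
    # enforce exact boundary behaviour: C(u,0)=0, C(u,1)=u, C(1,v)=v
    out = np.where((u_b == 0) | (v_b == 0), 0.0, out)
    out = np.where(v_b == 1, u_b, out)
    out = np.where(u_b == 1, np.where(v_b == 1, 1.0, v_b), out)
    return float(out[0]) if scalar else out.reshape(np.broadcast(u, v).shape)


def copula_pdf(family: str, gamma, u, v):
    """Copula density c(u, v; gamma) on the open unit square."""
    if family == "independence":
        return np.ones_like(np.broadcast_arrays(np.asarray(u, float), np.asarray(v, float))[0])
    cop = _make(family, gamma)
    uu = np.clip(np.asarray(u, float), CLIP_EPS, 1 - CLIP_EPS)
    vv = np.clip(np.asarray(v, float), CLIP_EPS, 1 - CLIP_EPS)
    out = np.asarray(cop.pdf(np.column_stack([np.ravel(uu), np.ravel(vv)])), dtype=float)
    return out.reshape(np.broadcast(uu, vv).shape)


def copula_rvs(family: str, gamma, n: int, rng) -> np.ndarray:
    """Draw ``n`` pairs from the copula.  ``rng`` is a numpy Generator or seed."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if family == "independence":
        return rng.uniform(size=(n, 2))
    if family == "frank" and gamma < 0:
        # reflection symmetry: (U, 1-V) ~ Frank(-gamma)
        uv = np.asarray(_make("frank", -gamma).rvs(n, random_state=rng))
        uv[:, 1] = 1.0 - uv[:, 1]
        return uv
    cop = _make(family, gamma)
    return np.asarray(cop.rvs(n, random_state=rng))


@dataclass
class CopulaModel:
    """A fitted copula: family, dependence parameter, and fit diagnostics."""

    family: str
    gamma: float | None
    loglik: float
    n_obs: int
    gof_statistic: float | None = None
    gof_pvalue: float | None = None
    warnings: list[str] = field(default_factory=list)

    def cdf(self, u, v):
        return copula_cdf(self.family, self.gamma, u, v)

    def pdf(self, u, v):
        return copula_pdf(self.family, self.gamma, u, v)

    def rvs(self, n, rng):
        return copula_rvs(self.family, self.gamma, n, rng)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CopulaModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def pseudo_observations(income_model, medical_model, df) -> np.ndarray:
    """Marginal-CDF transforms (u_i, v_i) of (ln I_i, ln ME_i).

    u_i = G(ln I_i | x_i) under the fitted income margin, v_i likewise for
    medical expenditure; clipped to [1e-10, 1 - 1e-10] so copula densities
    stay finite.  Returns an (n, 2) array.
    """
    u = income_model.conditional_cdf_frame(df, np.log(df["i"].to_numpy(float)))
    v = medical_model.conditional_cdf_frame(df, np.log(df["me"].to_numpy(float)))
    return np.column_stack([
        np.clip(u, CLIP_EPS, 1 - CLIP_EPS),
        np.clip(v, CLIP_EPS, 1 - CLIP_EPS),
    ])


def _neg_loglik(family: str, pairs: np.ndarray):
    u, v = pairs[:, 0], pairs[:, 1]

    def nll(gamma: float) -> float:
        if family == "frank" and abs(gamma) < 1e-4:
            return 0.0  # independence limit: density 1
        with np.errstate(all="ignore"):
            dens = copula_pdf(family, gamma, u, v)
        if not np.all(np.isfinite(dens)) or np.any(dens <= 0):
            return np.inf
        return -float(np.sum(np.log(dens)))

    return nll


def fit_copula_mle(family: str, pairs: np.ndarray) -> CopulaModel:
    """Maximum-likelihood fit of the dependence parameter gamma.

    The margins are treated as known (their parameters fixed upstream), so
    the likelihood is the product of copula densities at the
    pseudo-observations.  One-dimensional bounded optimisation; a gamma at
    the admissibility boundary is recorded as a warning on the model.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    n = pairs.shape[0]
    if n < 30:
        raise ValueError(f"need at least 30 pairs, got {n}")
    if family == "independence":
        return CopulaModel("independence", None, 0.0, n)
    lo, hi = _FAMILIES[family][2]
    nll = _neg_loglik(family, pairs)
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    gamma = float(res.x)
    model = CopulaModel(family, gamma, -float(res.fun), n)
    span = hi - lo
    if min(gamma - lo, hi - gamma) < 1e-3 * span:
        msg = f"gamma estimate {gamma:.4f} at admissibility boundary for {family}"
        warnings.warn(msg)
        model.warnings.append(msg)
    return model


def empirical_copula(pairs: np.ndarray, at: np.ndarray | None = None) -> np.ndarray:
    """Empirical copula C_n evaluated at ``at`` (default: the sample points)."""
    pairs = np.asarray(pairs, float)
    at = pairs if at is None else np.asarray(at, float)
    le_u = pairs[None, :, 0] <= at[:, None, 0]
    le_v = pairs[None, :, 1] <= at[:, None, 1]
    return (le_u & le_v).mean(axis=1)


def gof_test(model: CopulaModel, pairs: np.ndarray, n_boot: int = 200,
             seed=None) -> tuple[float, float]:
    """Cramer-von Mises goodness-of-fit test with parametric bootstrap.

    The standard empirical-copula procedure: the pairs are rank-transformed
    to pseudo-observations r_i = rank/(n+1) (stable ordering breaks the rare
    post-clipping ties), the family parameter is re-estimated on them, and

        S_n = sum_i (C_n(r_i) - C(r_i; gamma_hat))^2

    compares the empirical copula with the fitted one.  The null
    distribution comes from resimulating n pairs from the fitted copula,
    rank-transforming, refitting, and recomputing S_n; the p-value is the
    share of bootstrap statistics at least as large as the observed one.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    pairs = np.asarray(pairs, float)
    n = pairs.shape[0]
    rng = np.random.default_rng(seed)

    def to_ranks(p: np.ndarray) -> np.ndarray:
        return stats.rankdata(p, axis=0, method="ordinal") / (n + 1)

    def fit_on(p: np.ndarray) -> CopulaModel:
        if model.family == "independence":
            return CopulaModel("independence", None, 0.0, n)
        return fit_copula_mle(model.family, p)

    def statistic(p: np.ndarray, m: CopulaModel) -> float:
        cn = empirical_copula(p)
        cf = m.cdf(p[:, 0], p[:, 1])
        return float(np.sum((cn - cf) ** 2))

    obs = to_ranks(pairs)
    fitted = fit_on(obs)
    s_obs = statistic(obs, fitted)
    s_boot = np.empty(n_boot)
    for b in range(n_boot):
        sample = to_ranks(copula_rvs(fitted.family, fitted.gamma, n, rng))
        s_boot[b] = statistic(sample, fit_on(sample))
    pvalue = float(np.mean(s_boot >= s_obs))
    return s_obs, pvalue


def select_copula(candidates, pairs: np.ndarray, n_boot: int = 200,
                  seed=None, alpha: float = 0.05) -> CopulaModel:
    """Fit every candidate family, GOF-test each, and pick the best.

    Among families not rejected at level ``alpha`` the one with the highest
    log-likelihood wins; if all are rejected, the one with the largest
    p-value is returned with a warning.  The decision trace is attached to
    the returned model's ``warnings``.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    rng = np.random.default_rng(seed)
    fitted: list[CopulaModel] = []
    trace: list[str] = []
    for fam in candidates:
        m = (CopulaModel("independence", None, 0.0, len(pairs))
             if fam == "independence" else fit_copula_mle(fam, pairs))
        m.gof_statistic, m.gof_pvalue = gof_test(
            m, pairs, n_boot=n_boot, seed=rng.integers(2**31))
        trace.append(f"{fam}: loglik={m.loglik:.2f}, gof_p={m.gof_pvalue:.3f}")
        fitted.append(m)
    accepted = [m for m in fitted if m.gof_pvalue >= alpha]
    if accepted:
        best = max(accepted, key=lambda m: m.loglik)
    else:
        best = max(fitted, key=lambda m: m.gof_pvalue)
        msg = "all candidate families rejected at alpha=%.2f; returning largest p-value" % alpha
        warnings.warn(msg)
        best.warnings.append(msg)
    best.warnings.extend(trace)
    return best
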