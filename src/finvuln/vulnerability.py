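"""The ex ante financial-vulnerability measure.

A household is in financial distress when its financial margin
FM = I - DP - BLC is negative AND its liquid assets cannot cover the medical
expenditure, LA < ME.  With income and medical expenditure random, the
vulnerability of household i is the joint probability

    Delta_i = P(ln I < ln(DP + BLC),  ln ME > ln LA | x_i, y_i)

under the copula-coupled conditional-normal margins.  Writing
u* = G(ln(DP+BLC) | x) and v* = H(ln LA | y), the rectangle identity
P(U <= u*, V > v*) = u* - C(u*, v*) evaluates the double integral of the
joint density exactly; that closed form is the default method.  An adaptive
quadrature of the joint density and a Monte Carlo sampler are provided as
independent cross-checks.

LA = 0 is legal: the asset threshold is -inf, v* = 0, and Delta reduces to
the marginal probability of a negative financial margin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .copula import CopulaModel, copula_pdf, copula_rvs

LABOR_BIN_EDGES = [0.0, 0.25, 0.5, 0.75, np.inf]
LABOR_BIN_LABELS = ["<0.25", "0.25-0.5", "0.5-0.75", ">=0.75"]
EDUCATION_BIN_EDGES = [0.0, 6.0, 9.0, 12.0, 15.0, np.inf]
EDUCATION_BIN_LABELS = ["<6", "6-9", "9-12", "12-15", ">=15"]
HEALTH_LABELS = {1: "excellent", 2: "very good", 3: "good", 4: "fair",
                 5: "poor", 6: "very poor"}


def thresholds(dp, la, blc) -> tuple[np.ndarray, np.ndarray]:
    """Log-scale cutoffs a = ln(DP + BLC) and b = ln(LA) (LA=0 -> -inf)."""
    dp = np.asarray(dp, dtype=float)
    la = np.asarray(la, dtype=float)
    base = dp + blc
    if np.any(base <= 0):
        raise ValueError("DP + BLC must be positive for every household")
    a = np.log(base)
    with np.errstate(divide="ignore"):
        b = np.where(la > 0, np.log(np.maximum(la, 1e-300)), -np.inf)
    return a, b


def delta_from_uv(u_star, v_star, copula: CopulaModel):
    """Delta = u* - C(u*, v*): probability of {U <= u*, V > v*}."""
    u_star = np.asarray(u_star, dtype=float)
    v_star = np.asarray(v_star, dtype=float)
    return np.clip(u_star - copula.cdf(u_star, v_star), 0.0, 1.0)


def distress_probability(income_model, medical_model, copula: CopulaModel,
                         records: pd.DataFrame, blc: float) -> pd.DataFrame:
    """Closed-form vulnerability for every row of ``records``.

    Returns a frame with household_id, wave, stratum, the two log-scale
    thresholds, ``delta``, and ``method = "closed_form"``.
    """
    a, b = thresholds(records["dp"], records["la"], blc)
    u_star = income_model.conditional_cdf_frame(records, a)
    # b = -inf maps to v* = 0 exactly
    v_star = np.where(np.isfinite(b),
                      medical_model.conditional_cdf_frame(records,
                                                          np.where(np.isfinite(b), b, 0.0)),
                      0.0)
    delta = delta_from_uv(u_star, v_star, copula)
    return pd.DataFrame({
        "household_id": records["household_id"].to_numpy(),
        "wave": records["wave"].to_numpy(),
        "stratum": records["stratum"].to_numpy(),
        "a_threshold": a,
        "b_threshold": b,
        "delta": delta,
        "method": "closed_form",
    })


def distress_probability_single(income_model, medical_model, copula, x, y,
                                dp: float, la: float, blc: float) -> float:
    """Closed-form Delta for one household given its covariate vectors."""
    a, b = thresholds(dp, la, blc)
    u_star = income_model.conditional_cdf(x, float(a))
    v_star = medical_model.conditional_cdf(y, float(b)) if np.isfinite(b) else 0.0
    return float(delta_from_uv(u_star, v_star, copula))


def distress_probability_quadrature(income_model, medical_model, copula, x, y,
                                    dp: float, la: float, blc: float,
                                    epsabs: float = 1e-8) -> float:
    """Adaptive 2-D quadrature of the joint density over the distress region.

    Integrates c(G(u), H(v)) g(u) h(v) over u in (-inf, a], v in [b, +inf)
    on the log scale; retained as an independent oracle for the closed form.
    """
    a, b = thresholds(dp, la, blc)
    a, b = float(a), float(b)
    mi, si = income_model.conditional_mean(x), np.sqrt(income_model.conditional_variance(x))
    mm, sm_ = medical_model.conditional_mean(y), np.sqrt(medical_model.conditional_variance(y))

    def integrand(v, u):
        gu = stats.norm.cdf(u, mi, si)
        hv = stats.norm.cdf(v, mm, sm_)
        dens = copula_pdf(copula.family, copula.gamma, gu, hv)
        return float(dens) * stats.norm.pdf(u, mi, si) * stats.norm.pdf(v, mm, sm_)

    lo_u = mi - 10 * si
    if a <= lo_u:
        return 0.0
    hi_v = mm + 10 * sm_
    lo_v = b if np.isfinite(b) else mm - 10 * sm_
    if lo_v >= hi_v:
        return 0.0
    val, err = integrate.dblquad(integrand, lo_u, a, lo_v, hi_v,
                                 epsabs=epsabs, epsrel=1e-10)
    if not np.isfinite(val) or err > max(1e-6, 10 * epsabs):
        raise RuntimeError(f"quadrature did not converge (value={val}, err={err})")
    return float(val)


def distress_probability_mc(income_model, medical_model, copula, x, y,
                            dp: float, la: float, blc: float,
                            n_draws: int = 10**6, rng=None) -> float:
    """Monte Carlo estimate: simulate (I, ME) and count distress events."""
    rng = np.random.default_rng(rng)
    a, b = thresholds(dp, la, blc)
    uv = copula_rvs(copula.family, copula.gamma, n_draws, rng)
    mi, si = income_model.conditional_mean(x), np.sqrt(income_model.conditional_variance(x))
    mm, sm_ = medical_model.conditional_mean(y), np.sqrt(medical_model.conditional_variance(y))
    ln_i = mi + si * stats.norm.ppf(uv[:, 0])
    ln_me = mm + sm_ * stats.norm.ppf(uv[:, 1])
    return float(np.mean((ln_i < float(a)) & (ln_me > float(b))))


def gaussian_orthant_delta(a_tilde: float, b_tilde: float, gamma: float) -> float:
    """Bivariate-normal oracle Phi(a) - Phi2(a, b; gamma) for the Gaussian copula.

    ``a_tilde`` and ``b_tilde`` are the standardized thresholds
    (a - mean)/sd on each margin.
    """
    if not np.isfinite(b_tilde):
        if b_tilde < 0:  # asset condition always satisfied
            return float(stats.norm.cdf(a_tilde))
        return 0.0
    biv = stats.multivariate_normal(mean=[0.0, 0.0],
                                    cov=[[1.0, gamma], [gamma, 1.0]])
    return float(stats.norm.cdf(a_tilde) - biv.cdf([a_tilde, b_tilde]))


def group_summary(results: pd.DataFrame, grouping: str,
                  records: pd.DataFrame) -> pd.DataFrame:
    """Mean vulnerability by group within each (stratum, wave) cell.

    ``grouping`` is one of ``health_status`` (the six self-reported levels),
    ``labor_bins`` (<0.25, 0.25-0.5, 0.5-0.75, >=0.75), or
    ``education_bins`` (<6, 6-9, 9-12, 12-15, >=15).  Bins are half-open
    [lo, hi) with the last closed above.
    """
    merged = results.merge(
        records[["household_id", "wave"] +
                [c for c in ("health", "labor", "education") if c in records.columns]],
        on=["household_id", "wave"], how="left")
    if grouping == "health_status":
        merged["group"] = merged["health"].map(HEALTH_LABELS)
        order = list(HEALTH_LABELS.values())
    elif grouping == "labor_bins":
        merged["group"] = pd.cut(merged["labor"], LABOR_BIN_EDGES,
                                 labels=LABOR_BIN_LABELS, right=False,
                                 include_lowest=True)
        order = LABOR_BIN_LABELS
    elif grouping == "education_bins":
        merged["group"] = pd.cut(merged["education"], EDUCATION_BIN_EDGES,
                                 labels=EDUCATION_BIN_LABELS, right=False,
                                 include_lowest=True)
        order = EDUCATION_BIN_LABELS
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    table = (merged.groupby(["group", "stratum", "wave"], observed=False)["delta"]
             .mean().unstack(["stratum", "wave"]))
    return table.reindex(order)
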