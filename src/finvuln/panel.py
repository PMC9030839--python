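"""Determinant regressions for the vulnerability panel.

The continuous vulnerability score Delta_it is regressed on household
determinants by three estimators: pooled OLS on the stacked panel, the
within (fixed-effects) estimator after entity demeaning, and Swamy-Arora
random effects (feasible GLS with variance components).  Specification
tests: the individual-effect F test (pooled vs. within), the Hausman test
(FE vs. RE), and a Chow test for coefficient stability across two
wave windows.  Standard errors are conventional (unadjusted), matching how
such household panels are usually reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PanelEstimates:
    """Coefficients, standard errors, and fit metadata for one estimator."""

    estimator: str
    coefficients: dict
    standard_errors: dict
    cov: np.ndarray
    r_squared: float
    ssr: float
    n_obs: int
    n_entities: int
    df_resid: int
    dropped: list[str] = field(default_factory=list)
    tests: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.coefficients)

    def pvalues(self) -> dict:
        out = {}
        for name in self.coefficients:
            se = self.standard_errors[name]
            if se == 0 or not np.isfinite(se):
                out[name] = np.nan
            else:
                t = self.coefficients[name] / se
                out[name] = 2 * stats.t.sf(abs(t), self.df_resid)
        return out

    def significance_markers(self) -> dict:
        """p<0.01 '**', p<0.05 '*', p<0.10 '+', else ''."""
        marks = {}
        for name, p in self.pvalues().items():
            marks[name] = ("**" if p < 0.01 else "*" if p < 0.05
                           else "+" if p < 0.10 else "")
        return marks


def _prepare(df: pd.DataFrame, covariate_names, depvar, entity, time):
    d = df.dropna(subset=[depvar] + list(covariate_names)).copy()
    d = d.sort_values([entity, time], kind="stable").reset_index(drop=True)
    y = d[depvar].to_numpy(float)
    X = d.loc[:, list(covariate_names)].to_numpy(float)
    return d, y, X


def _ols(y, X, names, df_resid=None):
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        u, s, vt = np.linalg.svd(X)
        bad = [names[j] for j in np.argsort(np.abs(vt[-1]))[::-1][:2]]
        raise np.linalg.LinAlgError(
            f"rank-deficient design; suspect collinear column(s): {', '.join(bad)}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    dfr = (n - k) if df_resid is None else df_resid
    s2 = ssr / dfr
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta, cov, resid, ssr, dfr


def fit_panel(df: pd.DataFrame, covariate_names, estimator: str,
              depvar: str = "delta", entity: str = "household_id",
              time: str = "wave") -> PanelEstimates:
    """Fit the vulnerability panel by one of {"pooled", "fixed", "random"}.

    The fixed-effects path drops covariates with no within-entity variation
    (a named warning); its reported constant is the grand-mean recentred
    intercept.  Random effects uses Swamy-Arora variance components.
    """
    covariate_names = list(covariate_names)
    d, y, X = _prepare(df, covariate_names, depvar, entity, time)
    n = len(d)
    n_waves = d[time].nunique()
    entities, ent_idx = np.unique(d[entity], return_inverse=True)
    n_ent = len(entities)

    if estimator == "pooled":
        names = ["const"] + covariate_names
        Z = np.column_stack([np.ones(n), X])
        beta, cov, resid, ssr, dfr = _ols(y, Z, names)
        tss = float(((y - y.mean()) ** 2).sum())
        return PanelEstimates(
            "pooled", dict(zip(names, beta)),
            dict(zip(names, np.sqrt(np.diag(cov)))), cov,
            1 - ssr / tss, ssr, n, n_ent, dfr)

    if estimator not in ("fixed", "random"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if n_waves < 2:
        raise ValueError(f"{estimator} effects need >= 2 waves, got {n_waves}")

    # entity means
    counts = np.bincount(ent_idx)
    ybar = np.bincount(ent_idx, weights=y) / counts
    Xbar = np.vstack([np.bincount(ent_idx, weights=X[:, j]) / counts
                      for j in range(X.shape[1])]).T

    if estimator == "fixed":
        Xw = X - Xbar[ent_idx]
        keep, dropped = [], []
        for j, name in enumerate(covariate_names):
            if np.allclose(Xw[:, j], 0.0, atol=1e-12):
                dropped.append(name)
            else:
                keep.append(j)
        if dropped:
            warnings.warn("no within-entity variation; dropped: " + ", ".join(dropped))
        kept_names = [covariate_names[j] for j in keep]
        yw = y - ybar[ent_idx]
        k = len(keep)
        dfr = n - n_ent - k
        beta, cov, resid, ssr, dfr = _ols(yw, Xw[:, keep], kept_names, df_resid=dfr)
        # grand-mean recentred intercept; its SE from the recentred regression
        const = float(y.mean() - X[:, keep].mean(axis=0) @ beta)
        xc = X[:, keep].mean(axis=0)
        se_const = float(np.sqrt(ssr / dfr / n + xc @ cov @ xc))
        tss_w = float((yw**2).sum())
        coefs = {"const": const, **dict(zip(kept_names, beta))}
        ses = {"const": se_const, **dict(zip(kept_names, np.sqrt(np.diag(cov))))}
        return PanelEstimates("fixed", coefs, ses, cov,
                              1 - ssr / tss_w if tss_w > 0 else np.nan,
                              ssr, n, n_ent, dfr, dropped=dropped)

    # random effects (Swamy-Arora)
    k = X.shape[1]
    Xw = X - Xbar[ent_idx]
    keep_w = [j for j in range(k) if not np.allclose(Xw[:, j], 0.0, atol=1e-12)]
    yw = y - ybar[ent_idx]
    bw, *_ = np.linalg.lstsq(Xw[:, keep_w], yw, rcond=None)
    ssr_w = float(((yw - Xw[:, keep_w] @ bw) ** 2).sum())
    sigma2_e = ssr_w / (n - n_ent - len(keep_w))
    # between regression on entity means
    Zb = np.column_stack([np.ones(n_ent), Xbar])
    bb, *_ = np.linalg.lstsq(Zb, ybar, rcond=None)
    ssr_b = float(((ybar - Zb @ bb) ** 2).sum())
    t_bar = n / n_ent
    sigma2_b = ssr_b / max(n_ent - k - 1, 1)
    sigma2_u = max(sigma2_b - sigma2_e / t_bar, 0.0)
    lam = 1.0 - np.sqrt(sigma2_e / (sigma2_e + counts * sigma2_u))
    # quasi-demean (including the intercept column)
    yq = y - lam[ent_idx] * ybar[ent_idx]
    Xq = X - lam[ent_idx][:, None] * Xbar[ent_idx]
    cq = 1.0 - lam[ent_idx]
    names = ["const"] + covariate_names
    Z = np.column_stack([cq, Xq])
    beta, cov, resid, ssr, dfr = _ols(yq, Z, names)
    tss = float(((yq - yq.mean()) ** 2).sum())
    est = PanelEstimates(
        "random", dict(zip(names, beta)),
        dict(zip(names, np.sqrt(np.diag(cov)))), cov,
        1 - ssr / tss if tss > 0 else np.nan, ssr, n, n_ent, dfr)
    est.tests["variance_components"] = {"sigma2_e": sigma2_e, "sigma2_u": sigma2_u}
    return est


def hausman_test(fe: PanelEstimates, re: PanelEstimates) -> tuple[float, int, float]:
    """Hausman specification test on the common slope coefficients.

    Computes (b_FE - b_RE)' [V_FE - V_RE]^{-1} (b_FE - b_RE); a
    non-positive-definite covariance difference falls back to the
    Moore-Penrose pseudo-inverse with a warning.
    """
    common = [c for c in fe.coefficients if c != "const" and c in re.coefficients]
    if not common:
        raise ValueError("no common coefficients between FE and RE fits")
    fe_names = [c for c in fe.names if c != "const"]
    re_names = [c for c in re.names if c != "const"]
    # covariance matrices exclude the constant row/col where present
    V_fe = fe.cov
    if len(fe_names) != V_fe.shape[0]:
        raise ValueError("FE covariance does not match slope coefficients")
    i_fe = [fe_names.index(c) for c in common]
    i_re = [re_names.index(c) + 1 for c in common]  # +1 skips the const row
    b = np.array([fe.coefficients[c] - re.coefficients[c] for c in common])
    V = V_fe[np.ix_(i_fe, i_fe)] - re.cov[np.ix_(i_re, i_re)]
    eig = np.linalg.eigvalsh(V)
    if eig.min() <= 0:
        warnings.warn("V_FE - V_RE not positive definite; using pseudo-inverse")
        Vinv = np.linalg.pinv(V)
    else:
        Vinv = np.linalg.inv(V)
    stat = float(b @ Vinv @ b)
    df = len(common)
    return stat, df, float(stats.chi2.sf(stat, df))


def f_test_individual_effects(pooled: PanelEstimates,
                              fixed: PanelEstimates) -> tuple[float, tuple, float]:
    """F test of zero entity effects: pooled vs. within residual sums of squares."""
    if pooled.n_obs != fixed.n_obs:
        raise ValueError("pooled and fixed fits use different samples")
    n, n_ent = fixed.n_obs, fixed.n_entities
    k = len([c for c in fixed.coefficients if c != "const"])
    df1, df2 = n_ent - 1, n - n_ent - k
    stat = ((pooled.ssr - fixed.ssr) / df1) / (fixed.ssr / df2)
    stat = max(stat, 0.0)
    return float(stat), (df1, df2), float(stats.f.sf(stat, df1, df2))


def chow_test(df: pd.DataFrame, covariate_names, split,
              depvar: str = "delta", time: str = "wave") -> tuple[float, tuple, float]:
    """Chow F test of coefficient equality across two wave windows.

    ``split`` is a pair of wave collections, e.g. ``((2011, 2013), (2013, 2015))``.
    Pooled OLS is fit on each window and on their concatenation; the classical
    F statistic compares the restricted and unrestricted residual sums of
    squares with (K+1, n_A + n_B - 2K - 2) degrees of freedom.
    """
    waves_a, waves_b = split
    sub_a = df[df[time].isin(waves_a)]
    sub_b = df[df[time].isin(waves_b)]
    if len(sub_a) == 0 or len(sub_b) == 0:
        raise ValueError("empty subsample in Chow split")
    covariate_names = list(covariate_names)
    k1 = len(covariate_names) + 1

    def ssr_of(sub):
        y = sub[depvar].to_numpy(float)
        Z = np.column_stack([np.ones(len(sub)),
                             sub.loc[:, covariate_names].to_numpy(float)])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        return float(((y - Z @ beta) ** 2).sum())

    ssr_a, ssr_b = ssr_of(sub_a), ssr_of(sub_b)
    ssr_pooled = ssr_of(pd.concat([sub_a, sub_b]))
    df2 = len(sub_a) + len(sub_b) - 2 * k1
    stat = ((ssr_pooled - ssr_a - ssr_b) / k1) / ((ssr_a + ssr_b) / df2)
    stat = max(stat, 0.0)
    return float(stat), (k1, df2), float(stats.f.sf(stat, k1, df2))
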