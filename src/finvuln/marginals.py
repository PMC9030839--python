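"""Conditional-normal margins for log income and log medical expenditure.

The outcome model is log-linear with covariate-dependent variance:

    ln y_i = b' x_i + e_i,   e_i ~ N(0, s2_i),   s2_i = t' x_i

estimated by the three-step feasible GLS procedure standard in the
vulnerability-to-poverty literature:

1. OLS of ln y on x gives residuals e_hat.
2. OLS of e_hat^2 on x gives a provisional variance fit f_i; both sides are
   then divided by f_i (a weighted re-estimation with weights 1/f_i^2),
   giving the variance coefficients t_hat.  Non-positive f_i are floored at
   ``variance_floor`` before weighting.
3. The mean equation is re-estimated by least squares with each row scaled
   by 1 / sqrt(t_hat' x_i), giving the efficient mean coefficients b_hat.

The implied margin is ln y | x ~ N(b_hat' x, max(t_hat' x, floor)).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

_OUTCOME_COLUMN = {"income": "i", "medical": "me"}


def _design(df: pd.DataFrame, covariate_names) -> np.ndarray:
    missing = [c for c in covariate_names if c not in df.columns]
    if missing:
        raise KeyError(f"records lack covariate(s): {', '.join(missing)}")
    X = df.loc[:, list(covariate_names)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), X])


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        all_names = ["const"] + list(names)
        bad = [all_names[piv[j]] for j in range(len(diag)) if diag[j] <= tol]
        raise np.linalg.LinAlgError(
            f"design matrix rank deficient; collinear column(s): {', '.join(bad)}"
        )


@dataclass
class MarginalModel:
    """Fitted conditional-normal margin for one log outcome.

    ``mean_coefs`` and ``var_coefs`` are ordered (intercept, *covariates*);
    lengths equal ``len(covariate_names) + 1``.
    """

    outcome: str
    covariate_names: list[str]
    mean_coefs: np.ndarray
    var_coefs: np.ndarray
    n_obs: int
    variance_floor: float = 1e-4
    mean_se: np.ndarray | None = None
    var_se: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean_coefs = np.asarray(self.mean_coefs, dtype=float)
        self.var_coefs = np.asarray(self.var_coefs, dtype=float)
        k = len(self.covariate_names) + 1
        if len(self.mean_coefs) != k or len(self.var_coefs) != k:
            raise ValueError("coefficient vectors must have length n_covariates + 1")

    # -- single covariate vector -------------------------------------------
    def _augment(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 1 or len(x) != len(self.covariate_names):
            raise ValueError(
                f"expected covariate vector of length {len(self.covariate_names)}"
            )
        return np.concatenate([[1.0], x])

    def conditional_mean(self, x) -> float:
        """E[ln y | x] = intercept + coefficients . x."""
        return float(self._augment(x) @ self.mean_coefs)

    def conditional_variance(self, x) -> float:
        """V[ln y | x] = t_hat . x, floored at ``variance_floor``."""
        raw = float(self._augment(x) @ self.var_coefs)
        if raw <= self.variance_floor:
            warnings.warn(
                f"predicted variance {raw:.3g} floored at {self.variance_floor}"
            )
            return self.variance_floor
        return raw

    def conditional_cdf(self, x, value: float) -> float:
        """P(ln y <= value | x) under the fitted normal margin."""
        m = self.conditional_mean(x)
        s2 = self.conditional_variance(x)
        return float(stats.norm.cdf((value - m) / np.sqrt(s2)))

    # -- vectorised over a panel frame -------------------------------------
    def mean_frame(self, df: pd.DataFrame) -> np.ndarray:
        return _design(df, self.covariate_names) @ self.mean_coefs

    def variance_frame(self, df: pd.DataFrame) -> np.ndarray:
        raw = _design(df, self.covariate_names) @ self.var_coefs
        return np.maximum(raw, self.variance_floor)

    def conditional_cdf_frame(self, df: pd.DataFrame, values) -> np.ndarray:
        z = (np.asarray(values, float) - self.mean_frame(df)) / np.sqrt(
            self.variance_frame(df)
        )
        return stats.norm.cdf(z)

    # -- serialisation ------------------------------------------------------
    def to_json(self, path) -> None:
        d = asdict(self)
        names = ["const"] + list(self.covariate_names)
        for key in ("mean_coefs", "var_coefs", "mean_se", "var_se"):
            vec = getattr(self, key)
            d[key] = None if vec is None else dict(zip(names, np.asarray(vec).tolist()))
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MarginalModel":
        with open(path) as fh:
            d = json.load(fh)
        names = ["const"] + list(d["covariate_names"])
        for key in ("mean_coefs", "var_coefs", "mean_se", "var_se"):
            if d.get(key) is not None:
                d[key] = np.array([d[key][c] for c in names])
        return cls(**d)


def fit_fgls(df: pd.DataFrame, outcome: str, covariate_names,
             variance_floor: float = 1e-4) -> MarginalModel:
    """Three-step FGLS fit of a conditional-normal margin.

    Parameters
    ----------
    df : DataFrame
        Validated panel rows (one stratum-wave cell or a pooled sample).
    outcome : {"income", "medical"}
        Which strictly positive outcome column to model (``i`` or ``me``).
    covariate_names : sequence of str
        Regressors of both the mean and the variance equation.
    variance_floor : float
        Lower bound for fitted variances; floored predictions are counted
        in ``diagnostics["n_floored"]``.
    """
    if outcome not in _OUTCOME_COLUMN:
        raise ValueError("outcome must be 'income' or 'medical'")
    covariate_names = list(covariate_names)
    y_raw = df[_OUTCOME_COLUMN[outcome]].to_numpy(dtype=float)
    if np.any(y_raw <= 0):
        raise ValueError(f"{outcome} outcome must be strictly positive")
    X = _design(df, covariate_names)
    n, k = X.shape
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} observations, got {n}")
    _check_rank(X, covariate_names)
    y = np.log(y_raw)

    # step 1: OLS mean fit
    step1 = sm.OLS(y, X).fit()
    resid = y - X @ step1.params

    # step 2: variance equation, then FGLS re-estimation of it
    e2 = resid**2
    prov = sm.OLS(e2, X).fit()
    fitted = X @ prov.params
    w = np.maximum(fitted, variance_floor)
    step2 = sm.WLS(e2, X, weights=1.0 / w**2).fit()
    var_coefs = step2.params

    # step 3: weighted mean re-estimation with 1/sqrt(variance) row scaling
    sigma2 = np.maximum(X @ var_coefs, variance_floor)
    n_floored = int(np.sum(X @ var_coefs <= variance_floor))
    if n_floored == n:
        raise ValueError("variance model unusable: every prediction floored")
    step3 = sm.WLS(y, X, weights=1.0 / sigma2).fit()

    return MarginalModel(
        outcome=outcome,
        covariate_names=covariate_names,
        mean_coefs=np.asarray(step3.params),
        var_coefs=np.asarray(var_coefs),
        n_obs=n,
        variance_floor=variance_floor,
        mean_se=np.asarray(step3.bse),
        var_se=np.asarray(step2.bse),
        diagnostics={
            "r2_step1": float(step1.rsquared),
            "r2_variance": float(prov.rsquared),
            "n_floored": n_floored,
        },
    )
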