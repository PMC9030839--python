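import numpy as np
import pandas as pd
import pytest

import finvuln as fv
from finvuln.panel import PanelEstimates, fit_panel


def simulate_delta_panel(N, T, rng, slopes=(0.1, -0.2), sigma_u=0.05,
                         sigma_e=0.1, corr=0.0, shift=0.0, wave0=2011):
    """Linear panel y = Xb + entity effect + noise, 2 time-varying covariates.

    ``corr`` moves the covariates with the entity effect (RE-inconsistent
    world); ``shift`` adds a slope break in the last wave (for Chow power).
    """
    ent = rng.normal(0, sigma_u, N)
    rows = []
    for t in range(T):
        x = rng.normal(0, 1, (N, 2)) + corr * ent[:, None]
        b = np.asarray(slopes) + (shift if t == T - 1 else 0.0)
        y = x @ b + ent + rng.normal(0, sigma_e, N)
        rows.append(pd.DataFrame({"household_id": np.arange(N),
                                  "wave": wave0 + 2 * t,
                                  "x1": x[:, 0], "x2": x[:, 1], "delta": y}))
    return pd.concat(rows, ignore_index=True)


def test_fixed_and_random_recover_slopes_in_re_world(rng):
    """Uncorrelated entity effects: FE and RE both hit the true slopes."""
    df = simulate_delta_panel(800, 3, rng)
    for est in ("fixed", "random"):
        fit = fit_panel(df, ["x1", "x2"], est)
        for name, truth in (("x1", 0.1), ("x2", -0.2)):
            assert abs(fit.coefficients[name] - truth) < 3 * fit.standard_errors[name]


def test_pooled_biased_fixed_consistent_with_correlated_effects(rng):
    """Correlated effects bias pooled OLS but not the within estimator."""
    df = simulate_delta_panel(1500, 3, rng, sigma_u=0.3, sigma_e=0.3, corr=1.0)
    pooled = fit_panel(df, ["x1", "x2"], "pooled")
    fixed = fit_panel(df, ["x1", "x2"], "fixed")
    assert abs(pooled.coefficients["x1"] - 0.1) > 5 * pooled.standard_errors["x1"]
    assert abs(fixed.coefficients["x1"] - 0.1) < 3 * fixed.standard_errors["x1"]


def test_time_invariant_column_dropped_with_warning(rng):
    df = simulate_delta_panel(100, 3, rng)
    df["zcons"] = np.repeat(rng.normal(size=100), 3).reshape(100, -1, order="F").ravel()
    df = df.sort_values(["household_id", "wave"]).reset_index(drop=True)
    df["zcons"] = df.groupby("household_id")["x1"].transform("first")
    with pytest.warns(UserWarning, match="zcons"):
        fit = fit_panel(df, ["x1", "x2", "zcons"], "fixed")
    assert "zcons" not in fit.coefficients and fit.dropped == ["zcons"]


def test_within_residuals_orthogonal_to_entity_dummies(rng):
    df = simulate_delta_panel(50, 3, rng)
    fit = fit_panel(df, ["x1", "x2"], "fixed")
    d = df.sort_values(["household_id", "wave"]).reset_index(drop=True)
    X = d[["x1", "x2"]].to_numpy()
    y = d["delta"].to_numpy()
    ent = d["household_id"].to_numpy()
    slopes = np.array([fit.coefficients["x1"], fit.coefficients["x2"]])
    resid = y - X @ slopes
    # after removing entity means of the residual, each entity sum is ~0
    sums = pd.Series(resid).groupby(ent).apply(lambda s: s - s.mean()).groupby(level=0).sum()
    assert np.max(np.abs(sums.to_numpy())) < 1e-10


def test_single_wave_panel_rejected_for_effects(rng):
    df = simulate_delta_panel(50, 1, rng)
    with pytest.raises(ValueError, match="2 waves"):
        fit_panel(df, ["x1", "x2"], "fixed")
    with pytest.raises(ValueError, match="2 waves"):
        fit_panel(df, ["x1", "x2"], "random")
    fit_panel(df, ["x1", "x2"], "pooled")  # pooled still fine


def test_hausman_zero_for_identical_estimates():
    cov = np.eye(2) * 1e-4
    fe = PanelEstimates("fixed", {"x1": 0.1, "x2": 0.2}, {"x1": 0.01, "x2": 0.01},
                        cov, 0.5, 1.0, 100, 50, 48)
    re = PanelEstimates("random", {"const": 0.0, "x1": 0.1, "x2": 0.2},
                        {"const": 0.01, "x1": 0.01, "x2": 0.01},
                        np.eye(3) * 0.5e-4, 0.5, 1.0, 100, 50, 97)
    stat, df_, p = fv.hausman_test(fe, re)
    assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)
    assert df_ == 2


def test_hausman_power_under_correlated_effects(rng):
    """The Hausman test detects effects correlated with the covariates."""
    rejections = 0
    for _ in range(20):
        df = simulate_delta_panel(700, 3, rng, sigma_u=0.3, sigma_e=0.5, corr=1.0)
        fe = fit_panel(df, ["x1", "x2"], "fixed")
        re = fit_panel(df, ["x1", "x2"], "random")
        with np.errstate(all="ignore"):
            _, _, p = fv.hausman_test(fe, re)
        rejections += p < 0.05
    assert rejections >= 16  # > 80% power


def test_f_test_detects_large_entity_effects(rng):
    df = simulate_delta_panel(300, 3, rng, sigma_u=0.5)
    pooled = fit_panel(df, ["x1", "x2"], "pooled")
    fixed = fit_panel(df, ["x1", "x2"], "fixed")
    stat, (df1, df2), p = fv.f_test_individual_effects(pooled, fixed)
    assert df1 == 299 and p < 1e-10


def test_f_test_rejects_mismatched_samples(rng):
    df = simulate_delta_panel(100, 3, rng)
    pooled = fit_panel(df.head(250), ["x1", "x2"], "pooled")
    fixed = fit_panel(df, ["x1", "x2"], "fixed")
    with pytest.raises(ValueError, match="different samples"):
        fv.f_test_individual_effects(pooled, fixed)


def test_chow_zero_on_duplicated_subsample(rng):
    df = simulate_delta_panel(200, 1, rng)
    stat, _, p = fv.chow_test(df, ["x1", "x2"], ((2011,), (2011,)))
    assert stat == pytest.approx(0.0, abs=1e-10) and p > 0.999


def test_chow_detects_slope_shift(rng):
    rejections = 0
    for _ in range(20):
        df = simulate_delta_panel(400, 2, rng, sigma_u=0.0, shift=0.1)
        _, _, p = fv.chow_test(df, ["x1", "x2"], ((2011,), (2013,)))
        rejections += p < 0.05
    assert rejections >= 16


def test_chow_empty_subsample_rejected(rng):
    df = simulate_delta_panel(50, 2, rng)
    with pytest.raises(ValueError, match="empty"):
        fv.chow_test(df, ["x1", "x2"], ((2011,), (1999,)))


def test_significance_markers_follow_pvalues(rng):
    df = simulate_delta_panel(800, 3, rng, slopes=(0.5, 0.0))
    fit = fit_panel(df, ["x1", "x2"], "pooled")
    marks = fit.significance_markers()
    assert marks["x1"] == "**"
    assert marks["x2"] in ("", "+")
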