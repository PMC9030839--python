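import numpy as np
import pandas as pd
import pytest
from scipy import stats

import finvuln as fv
from finvuln.copula import CopulaModel
from finvuln.marginals import MarginalModel
from finvuln.vulnerability import (delta_from_uv, distress_probability,
                                   group_summary, thresholds)


def _std_normal_model(outcome="income"):
    names = ["income", "medical"]
    return MarginalModel(outcome, [], np.array([0.0]), np.array([1.0]), 100)


def _indep():
    return CopulaModel("independence", None, 0.0, 100)


def test_zero_liquid_assets_reduce_to_marginal(fitted_models, urban_panel):
    """LA = 0 makes Delta the probability of a negative financial margin."""
    income, medical, copula = fitted_models
    _, panel, _ = urban_panel
    rows = panel.head(5).copy()
    rows["la"] = 0.0
    res = distress_probability(income, medical, copula, rows, 4745.0)
    a, _ = thresholds(rows["dp"], rows["la"], 4745.0)
    expected = income.conditional_cdf_frame(rows, a)
    np.testing.assert_allclose(res["delta"], expected, atol=1e-12)
    assert np.all(np.isneginf(res["b_threshold"]))


def test_independence_standard_normal_quadrant():
    """a = b = 0 with standard-normal margins and independence gives 1/4."""
    im, mm = _std_normal_model("income"), _std_normal_model("medical")
    # thresholds at the medians: DP + BLC = 1 => a = 0; LA = 1 => b = 0
    d = fv.distress_probability_single(im, mm, _indep(), [], [],
                                       dp=0.0, la=1.0, blc=1.0)
    assert d == pytest.approx(0.25, abs=1e-12)


def test_gaussian_matches_bivariate_orthant_oracle(rng):
    """Closed form equals Phi(a) - Phi2(a, b; gamma) to 1e-10."""
    for _ in range(50):
        gamma = rng.uniform(-0.9, 0.9)
        a_t, b_t = rng.normal(size=2)
        cop = CopulaModel("gaussian", gamma, 0.0, 100)
        u_star = stats.norm.cdf(a_t)
        v_star = stats.norm.cdf(b_t)
        d = float(delta_from_uv(u_star, v_star, cop))
        oracle = fv.gaussian_orthant_delta(a_t, b_t, gamma)
        assert d == pytest.approx(oracle, abs=1e-10)


@pytest.mark.parametrize("family, gamma", [("gaussian", 0.4), ("clayton", 2.0),
                                           ("gumbel", 1.5), ("frank", -3.0)])
def test_closed_form_agrees_with_quadrature(family, gamma, fitted_models, urban_panel):
    income, medical, _ = fitted_models
    _, panel, _ = urban_panel
    cop = CopulaModel(family, gamma, 0.0, 100)
    row = panel.iloc[3]
    x = row[list(income.covariate_names)].to_numpy(float)
    y = row[list(medical.covariate_names)].to_numpy(float)
    closed = fv.distress_probability_single(income, medical, cop, x, y,
                                            row["dp"], row["la"], 4745.0)
    quad = fv.distress_probability_quadrature(income, medical, cop, x, y,
                                              row["dp"], row["la"], 4745.0)
    assert closed == pytest.approx(quad, abs=1e-6)


def test_closed_form_agrees_with_monte_carlo(fitted_models, urban_panel):
    income, medical, copula = fitted_models
    _, panel, _ = urban_panel
    row = panel.iloc[10]
    x = row[list(income.covariate_names)].to_numpy(float)
    y = row[list(medical.covariate_names)].to_numpy(float)
    closed = fv.distress_probability_single(income, medical, copula, x, y,
                                            row["dp"], row["la"], 4745.0)
    n = 200_000
    mc = fv.distress_probability_mc(income, medical, copula, x, y,
                                    row["dp"], row["la"], 4745.0,
                                    n_draws=n, rng=77)
    se = np.sqrt(max(closed * (1 - closed), 1e-8) / n)
    assert abs(mc - closed) < 3 * se


def test_monotone_in_assets_debt_and_living_cost(fitted_models, urban_panel):
    """Delta falls as LA rises and rises with DP and BLC."""
    income, medical, copula = fitted_models
    _, panel, _ = urban_panel
    row = panel.iloc[4]
    x = row[list(income.covariate_names)].to_numpy(float)
    y = row[list(medical.covariate_names)].to_numpy(float)

    def d(dp=100.0, la=2000.0, blc=4745.0):
        return fv.distress_probability_single(income, medical, copula, x, y,
                                              dp, la, blc)

    la_grid = [d(la=v) for v in (500.0, 2000.0, 8000.0)]
    assert la_grid[0] > la_grid[1] > la_grid[2]
    dp_grid = [d(dp=v) for v in (0.0, 500.0, 5000.0)]
    assert dp_grid[0] < dp_grid[1] < dp_grid[2]
    blc_grid = [d(blc=v) for v in (2000.0, 4745.0, 9000.0)]
    assert blc_grid[0] < blc_grid[1] < blc_grid[2]


def test_delta_decreasing_in_dependence():
    """Stronger positive income-expenditure dependence lowers Delta.

    The distress event pairs a lower-tail income draw with an upper-tail
    expenditure draw; since Delta = u* - C(u*, v*; gamma) and the copula
    CDF is increasing in gamma for these families, Delta falls as the two
    shocks become more positively dependent (verified on a grid).
    """
    im, mm = _std_normal_model("income"), _std_normal_model("medical")
    for la in (np.exp(-1.0), 1.0, np.exp(1.0)):
        deltas = []
        for g in (0.0, 0.3, 0.6, 0.9):
            cop = CopulaModel("gaussian", g, 0.0, 100) if g else _indep()
            deltas.append(fv.distress_probability_single(
                im, mm, cop, [], [], dp=0.0, la=la, blc=np.exp(-1.0)))
        assert np.all(np.diff(deltas) < 0)


def test_mean_delta_matches_realized_frequency(urban_panel):
    """Ex ante probabilities average to the realized distress frequency."""
    spec, panel, truth = urban_panel
    rng = np.random.default_rng(99)
    cov = panel[list(fv.MEDICAL_COVARIATES)]
    i_new, me_new = fv.generate_outcomes(spec, panel, rng=rng)
    event = (i_new < panel["dp"] + spec.blc_per_capita) & (panel["la"] < me_new)
    d = np.asarray(truth["delta_true"])
    se = np.sqrt(np.sum(d * (1 - d))) / len(d)
    assert abs(event.mean() - d.mean()) < 3 * se + 1e-9


def test_group_summary_constant_deltas():
    records = pd.DataFrame({
        "household_id": list("abcd"), "wave": [2011] * 4,
        "stratum": ["urban"] * 4, "health": [1, 2, 3, 4],
        "labor": [0.1, 0.25, 0.5, 0.75], "education": [3, 6, 9, 15],
    })
    results = records[["household_id", "wave", "stratum"]].copy()
    results["delta"] = 0.1
    table = group_summary(results, "health_status", records)
    assert np.allclose(table.dropna(how="all").to_numpy(), 0.1, equal_nan=True)


def test_bin_edges_follow_half_open_convention():
    records = pd.DataFrame({
        "household_id": list("ab"), "wave": [2011] * 2, "stratum": ["urban"] * 2,
        "labor": [0.25, 0.75], "education": [6.0, 15.0], "health": [1, 1],
    })
    results = records[["household_id", "wave", "stratum"]].copy()
    results["delta"] = [0.2, 0.4]
    labor = group_summary(results, "labor_bins", records)
    assert labor.loc["0.25-0.5"].dropna().iloc[0] == pytest.approx(0.2)
    assert labor.loc[">=0.75"].dropna().iloc[0] == pytest.approx(0.4)
    edu = group_summary(results, "education_bins", records)
    assert edu.loc["6-9"].dropna().iloc[0] == pytest.approx(0.2)
    assert edu.loc[">=15"].dropna().iloc[0] == pytest.approx(0.4)
    with pytest.raises(ValueError, match="grouping"):
        group_summary(results, "income_bins", records)


def test_nonpositive_income_threshold_rejected():
    with pytest.raises(ValueError, match="DP \\+ BLC"):
        thresholds(-10.0, 100.0, 5.0)
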