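import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import finvuln as fv
from finvuln.copula import (CLIP_EPS, CopulaModel, copula_cdf, copula_rvs,
                            empirical_copula, fit_copula_mle, gof_test,
                            pseudo_observations, select_copula)

FAMILIES = [("gaussian", 0.4), ("clayton", 2.0), ("gumbel", 1.6), ("frank", 4.0)]


def test_gaussian_diagonal_closed_form():
    for g in (-0.5, 0.0, 0.3, 0.9):
        expected = 0.25 + np.arcsin(g) / (2 * np.pi)
        assert copula_cdf("gaussian", g, 0.5, 0.5) == pytest.approx(expected, abs=1e-8)


def test_independence_limit():
    u = np.array([0.1, 0.4, 0.7])
    v = np.array([0.9, 0.2, 0.5])
    np.testing.assert_allclose(copula_cdf("gaussian", 0.0, u, v), u * v, atol=1e-8)
    np.testing.assert_allclose(copula_cdf("independence", None, u, v), u * v)


@pytest.mark.parametrize("family, gamma", FAMILIES)
def test_uniform_margins(family, gamma):
    u = np.linspace(0.05, 0.95, 7)
    np.testing.assert_allclose(copula_cdf(family, gamma, u, 1.0), u, atol=1e-6)
    np.testing.assert_allclose(copula_cdf(family, gamma, 1.0, u), u, atol=1e-6)
    np.testing.assert_allclose(copula_cdf(family, gamma, u, 0.0), 0.0, atol=1e-12)


@pytest.mark.parametrize("family, gamma", FAMILIES)
def test_frechet_bounds_on_grid(family, gamma):
    grid = np.linspace(0.02, 0.98, 13)
    U, V = np.meshgrid(grid, grid)
    c = copula_cdf(family, gamma, U.ravel(), V.ravel())
    lower = np.maximum(U.ravel() + V.ravel() - 1, 0)
    upper = np.minimum(U.ravel(), V.ravel())
    assert np.all(c >= lower - 1e-9)
    assert np.all(c <= upper + 1e-9)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(u1=st.floats(0.01, 0.98), du=st.floats(0.001, 0.5),
       v1=st.floats(0.01, 0.98), dv=st.floats(0.001, 0.5),
       fam=st.sampled_from(FAMILIES))
def test_two_increasing_property(u1, du, v1, dv, fam):
    """C-volume of every rectangle is non-negative."""
    family, gamma = fam
    u2, v2 = min(u1 + du, 1.0), min(v1 + dv, 1.0)
    vol = (copula_cdf(family, gamma, u2, v2) - copula_cdf(family, gamma, u1, v2)
           - copula_cdf(family, gamma, u2, v1) + copula_cdf(family, gamma, u1, v1))
    assert vol >= -1e-9


def test_gaussian_mle_recovers_dependence(rng):
    pairs = copula_rvs("gaussian", 0.2, 10_000, rng)
    model = fit_copula_mle("gaussian", pairs)
    assert model.gamma == pytest.approx(0.2, abs=0.03)  # ~3x asymptotic SE
    # moment-estimator oracle: Pearson correlation of normal scores
    z = stats.norm.ppf(pairs)
    assert model.gamma == pytest.approx(np.corrcoef(z.T)[0, 1], abs=0.01)


def test_independent_pairs_give_near_zero_gamma(rng):
    pairs = rng.uniform(size=(10_000, 2))
    model = fit_copula_mle("gaussian", pairs)
    assert abs(model.gamma) < 3 / np.sqrt(len(pairs))


def test_mle_beats_independence(rng):
    pairs = copula_rvs("gaussian", 0.3, 500, rng)
    model = fit_copula_mle("gaussian", pairs)
    u, v = pairs[:, 0], pairs[:, 1]
    from finvuln.copula import copula_pdf
    ll0 = np.sum(np.log(copula_pdf("gaussian", 1e-12, u, v)))
    assert model.loglik >= ll0 - 1e-6


def test_mle_requires_enough_pairs(rng):
    with pytest.raises(ValueError, match="30"):
        fit_copula_mle("gaussian", rng.uniform(size=(10, 2)))


def test_pseudo_observations_at_conditional_means(fitted_models, urban_panel):
    """A record sitting exactly at both conditional means maps to (0.5, 0.5)."""
    income, medical, _ = fitted_models
    _, panel, _ = urban_panel
    row = panel.head(1).copy()
    row["i"] = np.exp(income.mean_frame(row))
    row["me"] = np.exp(medical.mean_frame(row))
    uv = pseudo_observations(income, medical, row)
    np.testing.assert_allclose(uv, [[0.5, 0.5]], atol=1e-12)


def test_pseudo_observations_uniform_under_truth(urban_panel):
    """With the true margins, the income pseudo-observations are uniform."""
    spec, panel, _ = urban_panel
    income_m, medical_m = spec.true_marginal_models()
    uv = pseudo_observations(income_m, medical_m, panel)
    assert stats.kstest(uv[:, 0], "uniform").pvalue > 0.01
    assert stats.kstest(uv[:, 1], "uniform").pvalue > 0.01


def test_clipping_engages_only_in_extreme_tails():
    """Clipping at 1e-10 corresponds to |z| above ~6.36."""
    z_edge = stats.norm.ppf(CLIP_EPS)
    assert z_edge == pytest.approx(-6.361, abs=0.01)
    assert stats.norm.cdf(-6.3) > CLIP_EPS     # not clipped
    assert stats.norm.cdf(-6.5) < CLIP_EPS     # clipped


def test_gof_statistic_nonnegative_and_reproducible(rng):
    pairs = copula_rvs("gaussian", 0.3, 200, rng)
    model = fit_copula_mle("gaussian", pairs)
    s1, p1 = gof_test(model, pairs, n_boot=25, seed=42)
    s2, p2 = gof_test(model, pairs, n_boot=25, seed=42)
    assert s1 >= 0 and (s1, p1) == (s2, p2)
    with pytest.raises(ValueError):
        gof_test(model, pairs, n_boot=0)


def test_empirical_copula_matches_definition(rng):
    pairs = rng.uniform(size=(50, 2))
    cn = empirical_copula(pairs)
    i = 7
    manual = np.mean((pairs[:, 0] <= pairs[i, 0]) & (pairs[:, 1] <= pairs[i, 1]))
    assert cn[i] == pytest.approx(manual)


def test_select_single_candidate_and_determinism(rng):
    pairs = copula_rvs("gaussian", 0.4, 400, rng)
    only = select_copula(["gaussian"], pairs, n_boot=20, seed=3)
    assert only.family == "gaussian"
    again = select_copula(["gaussian"], pairs, n_boot=20, seed=3)
    assert only.gamma == again.gamma and only.gof_pvalue == again.gof_pvalue


def test_select_prefers_generating_family(rng):
    pairs = copula_rvs("gaussian", 0.5, 2_000, rng)
    chosen = select_copula(["gaussian", "clayton"], pairs, n_boot=30, seed=9)
    assert chosen.family == "gaussian"


def test_gof_detects_clayton_tails_against_gaussian(rng):
    """Lower-tail-heavy Clayton data rejects a Gaussian fit at n = 2000."""
    theta = 2 * 0.4 / 0.6  # Kendall tau = 0.4
    rejections = 0
    for _ in range(6):
        pairs = copula_rvs("clayton", theta, 2000, rng)
        model = fit_copula_mle("gaussian", pairs)
        _, p = gof_test(model, pairs, n_boot=40, seed=rng.integers(2**31))
        rejections += p < 0.05
    assert rejections >= 5


def test_copula_model_json_round_trip(tmp_path, rng):
    pairs = copula_rvs("gaussian", 0.3, 200, rng)
    model = fit_copula_mle("gaussian", pairs)
    model.to_json(tmp_path / "c.json")
    back = CopulaModel.from_json(tmp_path / "c.json")
    assert back.family == model.family and back.gamma == model.gamma


def test_inadmissible_gamma_rejected():
    with pytest.raises(ValueError, match="admissible"):
        copula_cdf("clayton", -1.0, 0.5, 0.5)
    with pytest.raises(ValueError, match="admissible"):
        copula_cdf("gaussian", 1.5, 0.5, 0.5)
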