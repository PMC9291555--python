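"""Average-derivative gradients and parametric-bootstrap inference."""

import numpy as np
import pandas as pd
import pytest

import ecograd as eg
from ecograd.dataset import ENVS, TRAITS
from ecograd.gradients import GradientEngine, _bootstrap_p


def intercept_only_surface(pop):
    spec = eg.SmoothSpec(traits=(), envs=(), include_interactions=False,
                         include_spatial=False, include_year=False)
    return eg.fit_surface(spec, pop)


def test_flat_surface_gives_exact_zeros(small_pop):
    surf = intercept_only_surface(small_pop)
    g = eg.compute_gradients(surf, small_pop)
    assert np.abs(g.beta).max() < 1e-8
    assert np.abs(g.gamma).max() < 1e-8
    assert np.abs(g.env).max() < 1e-8
    assert np.abs(g.eco).to_numpy().max() < 1e-8


def test_no_interaction_terms_give_zero_eco(small_pop):
    spec = eg.SmoothSpec(k_main=5, include_interactions=False,
                         include_spatial=False)
    surf = eg.fit_surface(spec, small_pop)
    g = eg.compute_gradients(surf, small_pop)
    # additive log-link surface still has nonzero response-scale mixed
    # derivatives (exp of a sum), but the log-scale interaction is zero;
    # eco entries stay an order below the main gradients
    assert np.abs(g.eco).to_numpy().max() < 1.0


def test_log_linear_recovery_within_bootstrap_uncertainty():
    """beta recovers b_i*sigma_i on data from a log-linear surface."""
    params = eg.default_params(n_plants=1500, seed=71, per_sd_quadratic={},
                               per_sd_interaction={}, spatial_effect=None)
    ds = eg.generate_population(params)
    spec = eg.SmoothSpec(k_main=5, k_interaction=4, k_spatial=4)
    surf = eg.fit_surface(spec, ds)
    tg = eg.true_gradients(params, ds)
    _, gs = eg.parametric_bootstrap(surf, ds, n_boot=50, seed=1)
    for t in TRAITS:
        assert abs(gs.beta[t] - tg.beta[t]) < 3 * gs.se["beta"][t], t
    for e in ENVS:
        assert abs(gs.env[e] - tg.env[e]) < 3 * gs.se["env"][e], e


def test_quadratic_and_interaction_recovery():
    """gamma and the 15 ecological gradients recover their generating
    values within 3 bootstrap SEs on one study-scale dataset."""
    params = eg.default_params(n_plants=1200, seed=7)
    ds = eg.generate_population(params)
    surf = eg.fit_surface(eg.SmoothSpec(k_main=5, k_interaction=4,
                                        k_spatial=6), ds)
    tg = eg.true_gradients(params, ds)
    _, gs = eg.parametric_bootstrap(surf, ds, n_boot=50, seed=2)
    for t in TRAITS:
        assert abs(gs.gamma[t] - tg.gamma[t]) < 3 * gs.se["gamma"][t], t
        for e in ENVS:
            assert (abs(gs.eco.loc[t, e] - tg.eco.loc[t, e])
                    < 3 * gs.se["eco"].loc[t, e]), (t, e)


def test_standardization_invariance_under_unit_change(small_pop,
                                                      tiny_spec):
    """mm -> cm on internode leaves its standardized gradients unchanged."""
    surf = eg.fit_surface(tiny_spec, small_pop)
    g1 = eg.compute_gradients(surf, small_pop)
    df = small_pop.df.copy()
    df["internode"] = df["internode"] / 10.0
    pop2 = eg.PopulationDataset(df, provenance={"recoded": True})
    g2 = eg.compute_gradients(eg.fit_surface(tiny_spec, pop2), pop2)
    assert g2.beta["internode"] == pytest.approx(g1.beta["internode"],
                                                 abs=1e-4)
    assert g2.gamma["internode"] == pytest.approx(g1.gamma["internode"],
                                                  abs=1e-4)
    for e in ENVS:
        assert g2.eco.loc["internode", e] == pytest.approx(
            g1.eco.loc["internode", e], abs=1e-4)


def test_halving_fd_step_leaves_gradients_unchanged(fitted_small,
                                                    small_pop):
    g1 = eg.compute_gradients(fitted_small, small_pop, rel_step=1e-4)
    g2 = eg.compute_gradients(fitted_small, small_pop, rel_step=5e-5)
    for a, b in [(g1.beta, g2.beta), (g1.gamma, g2.gamma),
                 (g1.env, g2.env)]:
        np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-7)
    np.testing.assert_allclose(g1.eco, g2.eco, rtol=1e-6, atol=1e-7)


def test_quadratic_surface_matches_classical_regression(small_pop):
    """Identity-link globally quadratic surface: averaged derivatives
    equal the regression coefficients (Morrissey-Sakrejda consistency)."""
    qs = eg.QuadraticRegressionSurface(small_pop)
    cg = eg.lande_arnold(small_pop)
    g = eg.compute_gradients(qs, small_pop)
    for t in TRAITS:
        assert g.beta[t] == pytest.approx(cg.beta_quadratic_model[t],
                                          abs=1e-6)
        assert g.gamma[t] == pytest.approx(cg.gamma[t], abs=1e-6)


def test_individual_gradient_accessors_agree(fitted_small, small_pop):
    g = eg.compute_gradients(fitted_small, small_pop)
    pd.testing.assert_series_equal(
        eg.linear_gradient(fitted_small, small_pop), g.beta)
    pd.testing.assert_frame_equal(
        eg.ecological_gradient(fitted_small, small_pop), g.eco)


def test_scaling_record_present(fitted_small, small_pop):
    g = eg.compute_gradients(fitted_small, small_pop)
    assert set(g.scaling_record) >= {"trait_sd", "env_sd", "mean_fitness",
                                     "fd_steps"}
    assert g.scaling_record["trait_sd"]["height"] == pytest.approx(
        small_pop.df["height"].std(ddof=1))


def test_zero_variance_trait_rejected(fitted_small, small_pop):
    df = small_pop.df.copy()
    df["stems"] = 2.0
    frozen = eg.PopulationDataset(df, provenance={})
    with pytest.raises(ValueError, match="stems"):
        eg.compute_gradients(fitted_small, frozen)


class TestParametricBootstrap:
    def test_degenerate_n_boot_rejected(self, fitted_small, small_pop):
        with pytest.raises(ValueError):
            eg.parametric_bootstrap(fitted_small, small_pop, n_boot=0,
                                    seed=0)

    def test_unknown_method_rejected(self, fitted_small, small_pop):
        with pytest.raises(ValueError):
            eg.parametric_bootstrap(fitted_small, small_pop, n_boot=5,
                                    seed=0, method="jackknife")

    def test_same_seed_identical_output(self, fitted_small, small_pop):
        b1, g1 = eg.parametric_bootstrap(fitted_small, small_pop,
                                         n_boot=12, seed=42)
        b2, g2 = eg.parametric_bootstrap(fitted_small, small_pop,
                                         n_boot=12, seed=42)
        np.testing.assert_array_equal(b1.beta, b2.beta)
        pd.testing.assert_series_equal(g1.se["beta"], g2.se["beta"])
        pd.testing.assert_frame_equal(g1.p["eco"], g2.p["eco"])

    def test_p_value_formula(self):
        reps = np.array([0.5, 0.2, -0.1, 0.3, 0.4])
        # above: 4, below: 1 -> p = 2*min(5, 2)/6
        assert _bootstrap_p(reps, 5) == pytest.approx(2 * 2 / 6)
        assert _bootstrap_p(np.abs(reps), 5) == pytest.approx(
            min(1.0, 2 * 1 / 6))
        assert _bootstrap_p(np.array([1.0, 1.0]), 2) == pytest.approx(
            2 * 1 / 3)

    def test_replicate_shapes_and_p_range(self, fitted_small, small_pop):
        boot, gs = eg.parametric_bootstrap(fitted_small, small_pop,
                                           n_boot=15, seed=3)
        assert boot.beta.shape == (15 - boot.n_dropped, len(TRAITS))
        assert boot.eco.shape[1:] == (len(TRAITS), len(ENVS))
        for key in ("beta", "gamma", "env"):
            assert ((gs.p[key] >= 0) & (gs.p[key] <= 1)).all()
            assert (gs.se[key] >= 0).all()

    def test_coefficient_method_tracks_resimulation(self, fitted_small,
                                                    small_pop):
        _, g_fast = eg.parametric_bootstrap(fitted_small, small_pop,
                                            n_boot=60, seed=4,
                                            method="coefficient")
        _, g_full = eg.parametric_bootstrap(fitted_small, small_pop,
                                            n_boot=60, seed=4)
        # the Gaussian-posterior approximation should agree on the order
        # of magnitude of every SE
        ratio = (g_fast.se["beta"] / g_full.se["beta"]).to_numpy()
        assert (ratio > 0.3).all() and (ratio < 3.0).all()


def test_engine_reuses_base_design(fitted_small, small_pop):
    eng = GradientEngine(fitted_small, small_pop)
    g1 = eng.evaluate()
    g2 = eng.evaluate(beta=np.asarray(fitted_small.beta))
    np.testing.assert_allclose(g1.beta, g2.beta, rtol=1e-12)
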