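"""Penalized-spline fitness surface: design, fit, prediction, year test."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import ecograd as eg
from ecograd.surface import _poisson_deviance, build_design


def intercept_only_spec():
    return eg.SmoothSpec(traits=(), envs=(), include_interactions=False,
                         include_spatial=False, include_year=False)


class TestDesign:
    def test_single_year_absorbed_in_intercept(self, tiny_spec):
        params = eg.default_params(n_plants=150, seed=13,
                                   year_effects={2016: 0.0})
        ds = eg.generate_population(params)
        X, builder = build_design(tiny_spec, ds)
        assert all(t.name != "year" for t in builder.terms)

    def test_two_years_give_one_dummy_column(self, tiny_spec, small_pop):
        X, builder = build_design(tiny_spec, small_pop)
        (year_term,) = [t for t in builder.terms if t.name == "year"]
        assert year_term.ncol == 1

    def test_smooth_blocks_sum_to_zero(self, tiny_spec, small_pop):
        X, builder = build_design(tiny_spec, small_pop)
        for t, sl in zip(builder.terms, builder.slices):
            if t.name.startswith(("s(", "ti(", "te(")):
                np.testing.assert_allclose(X[:, sl].sum(axis=0), 0.0,
                                           atol=1e-7, err_msg=t.name)

    def test_penalties_positive_semidefinite(self, tiny_spec, small_pop):
        _, builder = build_design(tiny_spec, small_pop)
        for sl, S in builder.penalty_list():
            vals = np.linalg.eigvalsh(S)
            assert vals.min() > -1e-8 * max(vals.max(), 1.0)

    def test_design_structurally_full_rank(self, tiny_spec, small_pop):
        """Blocks whose covariates have adequate support are mutually
        independent; conspecific density's sparsely populated upper
        levels (a handful of plants at 3+ neighbors) cannot support the
        full product space with five traits, a data- not
        construction-driven deficiency absorbed by the penalties."""
        X, builder = build_design(tiny_spec, small_pop)
        keep = np.hstack([
            np.arange(sl.start, sl.stop)
            for t, sl in zip(builder.terms, builder.slices)
            if "density" not in t.name or t.name == "s(density)"])
        Xs = X[:, keep]
        assert np.linalg.matrix_rank(Xs) == Xs.shape[1]

    def test_builder_reproduces_training_design(self, fitted_small,
                                                small_pop):
        np.testing.assert_array_equal(
            fitted_small.builder.build(small_pop.df), fitted_small.X)

    def test_empty_dataset_rejected(self, tiny_spec, small_params):
        empty = eg.generate_population(
            dataclasses.replace(small_params, n_plants=0))
        with pytest.raises(ValueError):
            build_design(tiny_spec, empty)


class TestFit:
    def test_null_data_explain_almost_nothing(self, tiny_spec):
        """Structureless Poisson fruits: deviance explained stays tiny."""
        params = eg.null_params(n_plants=2000, seed=21, spatial_effect=None,
                                year_effects={2016: 0.0})
        ds = eg.generate_population(params)
        surf = eg.fit_surface(tiny_spec, ds)
        assert eg.deviance_explained(surf) < 0.02

    def test_unpenalized_limit_matches_glm(self, small_pop):
        """With smoothing forced to zero the fit is an ordinary GLM
        (main-effects design, where the GLM itself is well-posed)."""
        spec = eg.SmoothSpec(k_main=5, include_interactions=False,
                             include_spatial=False,
                             select="fixed", fixed_lambda=0.0)
        surf = eg.fit_surface(spec, small_pop, ridge_scale=0.0)
        glm = sm.GLM(small_pop.df["fruits"].to_numpy(dtype=float), surf.X,
                     family=sm.families.Poisson()).fit(maxiter=200)
        scale = np.abs(glm.params).max()
        np.testing.assert_allclose(surf.beta, glm.params,
                                   atol=1e-6 * scale, rtol=1e-6)

    def test_log_linear_truth_recovered_as_well_as_glm_oracle(self):
        """Penalized predictions track the truth as well as an
        unpenalized GLM on the same basis."""
        params = eg.default_params(
            n_plants=2000, seed=31, per_sd_quadratic={},
            per_sd_interaction={}, spatial_effect=None,
            year_effects={2016: 0.0})
        ds = eg.generate_population(params)
        spec = eg.SmoothSpec(k_main=5, k_interaction=4, k_spatial=4)
        surf = eg.fit_surface(spec, ds)
        eta_true = ds.provenance["true_log_mu"]
        glm = sm.GLM(ds.df["fruits"].to_numpy(dtype=float), surf.X,
                     family=sm.families.Poisson()).fit(maxiter=200)
        rmse_pen = np.sqrt(np.mean((np.log(surf.mu) - eta_true) ** 2))
        rmse_glm = np.sqrt(np.mean((surf.X @ glm.params - eta_true) ** 2))
        assert rmse_pen < rmse_glm * 1.2
        assert rmse_pen < 0.2

    def test_deviance_never_exceeds_null(self, fitted_small):
        assert fitted_small.deviance <= fitted_small.null_deviance

    def test_nested_specs_decrease_deviance_at_fixed_smoothing(
            self, small_pop):
        kw = dict(k_main=5, k_interaction=4, k_spatial=4,
                  select="fixed", fixed_lambda=1.0)
        d0 = eg.fit_surface(eg.SmoothSpec(
            traits=(), envs=(), include_interactions=False,
            include_spatial=False, include_year=False), small_pop).deviance
        d1 = eg.fit_surface(eg.SmoothSpec(
            include_interactions=False, include_spatial=False,
            **kw), small_pop).deviance
        d2 = eg.fit_surface(eg.SmoothSpec(
            include_spatial=False, **kw), small_pop).deviance
        d3 = eg.fit_surface(eg.SmoothSpec(**kw), small_pop).deviance
        assert d0 >= d1 >= d2 >= d3

    def test_prediction_invariant_to_affine_recoding(self, small_pop,
                                                     tiny_spec):
        """Internode in cm instead of mm: same fitted response surface."""
        surf_mm = eg.fit_surface(tiny_spec, small_pop)
        df_cm = small_pop.df.copy()
        df_cm["internode"] = df_cm["internode"] / 10.0
        pop_cm = eg.PopulationDataset(df_cm, provenance={"recoded": True})
        surf_cm = eg.fit_surface(tiny_spec, pop_cm)
        np.testing.assert_allclose(surf_cm.mu, surf_mm.mu, rtol=1e-6)

    def test_gcv_selection_runs(self, small_pop):
        spec = eg.SmoothSpec(k_main=5, k_interaction=4, k_spatial=4,
                             select="gcv")
        surf = eg.fit_surface(spec, small_pop)
        assert 0.0 < eg.deviance_explained(surf) < 1.0

    def test_save_load_round_trip(self, fitted_small, small_pop, tmp_path):
        fitted_small.save(tmp_path / "m.bin")
        back = eg.FittedSurface.load(tmp_path / "m.bin")
        np.testing.assert_array_equal(back.beta, fitted_small.beta)
        np.testing.assert_allclose(back.predict_response(small_pop.df),
                                   fitted_small.predict_response(
                                       small_pop.df))


class TestDevianceExplained:
    def test_intercept_only_is_zero(self, small_pop):
        surf = eg.fit_surface(intercept_only_spec(), small_pop)
        assert eg.deviance_explained(surf) == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_recomputation(self, fitted_small):
        y, mu = fitted_small.y, fitted_small.mu
        dev = _poisson_deviance(y, mu)
        null = _poisson_deviance(y, np.full_like(y, y.mean()))
        assert eg.deviance_explained(fitted_small) == pytest.approx(
            (null - dev) / null, rel=1e-10)

    def test_zero_null_deviance_rejected(self, fitted_small):
        broken = dataclasses.replace(fitted_small, null_deviance=0.0)
        with pytest.raises(ValueError):
            eg.deviance_explained(broken)


class TestPredictProfile:
    def held_values(self, ds):
        held = {c: float(ds.df[c].median()) for c in
                eg.TRAITS + eg.ENVS + ["lon", "lat"]}
        held["year"] = sorted(ds.years)[0]
        return held

    def test_single_point_matches_direct_prediction(self, fitted_small,
                                                    small_pop):
        held = self.held_values(small_pop)
        value = float(small_pop.df["height"].quantile(0.3))
        prof = eg.predict_profile(fitted_small, "height",
                                  np.array([value]), held)
        rec = pd.DataFrame([{**held, "height": value}])
        direct = fitted_small.predict_response(rec)[0]
        assert prof["fit"].iloc[0] == pytest.approx(direct, rel=1e-10)

    def test_intercept_only_profile_is_flat(self, small_pop):
        surf = eg.fit_surface(intercept_only_spec(), small_pop)
        grid = np.linspace(10, 60, 7)
        prof = eg.predict_profile(surf, "height", grid, {})
        np.testing.assert_allclose(prof["fit"],
                                   np.exp(surf.beta[0]), rtol=1e-10)

    def test_extrapolation_flagged(self, fitted_small, small_pop):
        held = self.held_values(small_pop)
        hi = small_pop.df["height"].max()
        prof = eg.predict_profile(fitted_small, "height",
                                  np.array([hi - 1.0, hi + 5.0]), held)
        assert list(prof["extrapolated"]) == [False, True]
        assert np.isfinite(prof[["fit", "lo", "hi"]]).all().all()

    def test_missing_held_covariate_rejected(self, fitted_small):
        with pytest.raises(ValueError, match="held"):
            eg.predict_profile(fitted_small, "height", np.array([30.0]),
                               {"leaves": 80.0})

    def test_ci_brackets_fit(self, fitted_small, small_pop):
        held = self.held_values(small_pop)
        grid = np.linspace(small_pop.df["height"].quantile(0.1),
                           small_pop.df["height"].quantile(0.9), 9)
        prof = eg.predict_profile(fitted_small, "height", grid, held)
        assert (prof["lo"] < prof["fit"]).all()
        assert (prof["fit"] < prof["hi"]).all()
        assert (prof["lo"] > 0).all()


def _pop_with(years, fruits, template):
    df = template.df.copy()
    df["year"] = years
    df["fruits"] = fruits
    return eg.PopulationDataset(df, provenance={"synthetic": True})


class TestAnnualFitnessTest:
    def test_one_year_rejected(self):
        params = eg.default_params(n_plants=60, seed=2,
                                   year_effects={2016: 0.0})
        with pytest.raises(ValueError):
            eg.annual_fitness_test(eg.generate_population(params))

    def test_label_invariance(self, small_pop):
        res1 = eg.annual_fitness_test(small_pop)
        relabel = {y: y + 7 for y in small_pop.years}
        df = small_pop.df.copy()
        df["year"] = df["year"].map(relabel)
        res2 = eg.annual_fitness_test(
            eg.PopulationDataset(df, provenance={}))
        assert res1["p_value"] == pytest.approx(res2["p_value"], rel=1e-9)
        assert res1["lr_statistic"] == pytest.approx(res2["lr_statistic"],
                                                     rel=1e-9)

    def test_power_with_large_year_effect(self, small_pop, rng):
        """log-mean difference of 1.0 at n=400: essentially always
        detected at p < 0.001."""
        n = small_pop.n
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            years = np.where(rng.random(n) < 0.5, 2015, 2016)
            mu = np.where(years == 2015, 5.0, 5.0 * np.e)
            ds = _pop_with(years, rng.poisson(mu), small_pop)
            hits += eg.annual_fitness_test(ds)["p_value"] < 1e-3
        assert hits >= 99

    def test_type_i_error_calibrated(self, small_pop, rng):
        """Identical Poisson means across years: rejection ~ alpha."""
        n = small_pop.n
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            years = np.where(rng.random(n) < 0.5, 2015, 2016)
            ds = _pop_with(years, rng.poisson(8.0, size=n), small_pop)
            rejections += eg.annual_fitness_test(ds)["p_value"] < 0.05
        # binomial 95% band around 0.05 for 500 replicates
        assert 0.031 <= rejections / n_rep <= 0.071
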