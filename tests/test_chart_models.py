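"""LMS fitting, quantile-regression comparators and AIC selection."""

import numpy as np
import pytest

from placentile import chart_models as cm
from placentile import distributions as dist
from placentile import synthetic_data as sd

from conftest import model_from_curves


def _simulate_truth(n, seed, truth=None):
    truth = truth or sd.SeriesTruth(mu=(0.16, 0.22), sigma=(0.40, 0.45), nu=(0.45, 0.45))
    rng = np.random.default_rng(seed)
    spec = sd.TruthSpec()
    t = rng.choice(np.arange(79, 100), size=n, p=spec.ga_weights()).astype(float)
    mu, sg, nu, tau = truth.at(t)
    y = dist.quantile_arrays(rng.uniform(size=n), mu, sg, nu, tau, truth.family)
    return t, y, truth


class TestFitLms:
    def test_recovers_known_bcpe_truth(self):
        # truth inside the model class (log-linear mu and sigma, constant
        # nu/tau) so any remaining error is sampling noise
        from placentile import centile_tools as ct

        truth = model_from_curves("BCPEo", mu=(0.16, 0.22), sigma=(0.40, 0.45), nu=0.45, tau=2.0)
        rng = np.random.default_rng(21)
        spec = sd.TruthSpec()
        t = rng.choice(np.arange(79, 100), size=2000, p=spec.ga_weights()).astype(float)
        y = ct.simulate_from_model(truth, t, seed=rng)
        model = cm.fit_lms(t, y, "BCPEo")
        assert model.converged
        grid = np.arange(82.0, 97.0)
        truth_med = ct.centile_curve(truth, 0.5, grid)
        fit_med = np.array([dist.quantile(0.5, model.params_at(g)) for g in grid])
        rel = np.abs(fit_med - truth_med) / truth_med
        # the median-over-ages error is the robust recovery statistic; the
        # pointwise maximum is dominated by sampling noise at sparse ages
        assert np.median(rel) < 0.025
        assert np.max(rel) < 0.06
        sig_t = np.array([truth.params_at(g).sigma for g in grid])
        sig_f = np.array([model.params_at(g).sigma for g in grid])
        assert np.max(np.abs(sig_f - sig_t) / sig_t) < 0.10

    def test_nested_families_agree_when_tau_is_two(self):
        # truth has nu = 1, tau = 2: BCCGo is the true submodel of BCPEo, so
        # the AICs can differ by at most ~2 per extra effective df
        truth = sd.SeriesTruth(mu=(0.18, 0.22), sigma=(0.30, 0.30), nu=(1.0, 1.0), tau=(2.0, 2.0))
        t, y, _ = _simulate_truth(1500, seed=22, truth=truth)
        m_ccg = cm.fit_lms(t, y, "BCCGo")
        m_pe = cm.fit_lms(t, y, "BCPEo")
        edf_gap = abs(m_pe.total_edf - m_ccg.total_edf)
        assert abs(m_pe.aic - m_ccg.aic) <= 2.0 * edf_gap + 1.0

    def test_loglik_nondecreasing_over_cycles(self):
        t, y, _ = _simulate_truth(800, seed=23)
        model = cm.fit_lms(t, y, "BCPEo", edf_grid={"mu": [3], "sigma": [2], "nu": [1], "tau": [1]})
        path = np.array(model.fit_meta["loglik_path"])
        assert np.all(np.diff(path) >= -1e-6)

    def test_aic_definition(self):
        t, y, _ = _simulate_truth(600, seed=24)
        m = cm.fit_lms(t, y, "BCCGo", k=3.0, edf_grid={"mu": [3], "sigma": [2]})
        assert m.aic == pytest.approx(-2.0 * m.loglik + 3.0 * m.total_edf)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            cm.fit_lms(np.arange(30.0) + 79, np.full(30, 0.2), "BCPEo")

    def test_constant_response_rejected(self):
        t = np.linspace(79, 99, 100)
        with pytest.raises(cm.FitError):
            cm.fit_lms(t, np.full(100, 0.2), "BCPEo")

    def test_json_roundtrip_is_exact(self):
        t, y, _ = _simulate_truth(600, seed=25)
        m = cm.fit_lms(t, y, "BCCGo", edf_grid={"mu": [3], "sigma": [2]})
        text = m.to_json()
        m2 = cm.FittedChartModel.from_json(text)
        assert m2.to_json() == text
        grid = np.linspace(80, 98, 7)
        for g in grid:
            a, b = m.params_at(g), m2.params_at(g)
            assert (a.mu, a.sigma, a.nu, a.tau) == (b.mu, b.sigma, b.nu, b.tau)


class TestQuantileCurves:
    def test_intercept_only_median_is_sample_median(self):
        # the L1 location estimator: solve with a pure-intercept design
        rng = np.random.default_rng(31)
        y = rng.uniform(0, 1, 101)
        X = np.ones((101, 1))
        beta = cm._solve_check_loss_lp(X, y, 0.5)
        assert beta[0] == pytest.approx(np.median(y), abs=1e-9)

    def test_intercept_only_quartile_brute_force_oracle(self):
        # check-loss minimizer on {1..100} at q=0.25 vs exhaustive grid search
        y = np.arange(1.0, 101.0)
        X = np.ones((100, 1))
        beta = cm._solve_check_loss_lp(X, y, 0.25)
        grid = np.linspace(0.0, 101.0, 10101)
        losses = [np.sum((y - c) * (0.25 - (y < c))) for c in grid]
        oracle = grid[int(np.argmin(losses))]
        assert abs(beta[0] - oracle) <= 1.0  # flat region between order stats
        loss_fit = np.sum((y - beta[0]) * (0.25 - (y < beta[0])))
        assert loss_fit <= min(losses) + 1e-9

    def test_lasso_penalty_to_zero_matches_exact(self):
        rng = np.random.default_rng(32)
        t = rng.uniform(79, 99, 200)
        y = 0.1 + 0.003 * (t - 79) + 0.02 * rng.standard_normal(200)
        exact = cm.fit_quantile_curves(t, y, basis="poly2", solver="exact_L1")
        lasso = cm.fit_quantile_curves(t, y, basis="poly2", solver="lasso_penalized", penalty=1e-10)
        for q in exact.quantile_levels:
            grid = np.linspace(79, 99, 21)
            np.testing.assert_allclose(lasso.predict(grid, q), exact.predict(grid, q), atol=1e-4)

    def test_singular_design_named_error(self):
        t = np.full(100, 89.0)  # constant covariate: collinear columns
        y = np.random.default_rng(33).uniform(0, 1, 100)
        with pytest.raises(cm.FitError, match="poly2"):
            cm.fit_quantile_curves(t, y, basis="poly2")

    def test_non_crossing_rearrangement_sorted(self):
        rng = np.random.default_rng(34)
        t = rng.uniform(79, 99, 300)
        y = 0.2 + 0.05 * rng.standard_normal(300)
        m = cm.fit_quantile_curves(t, y, basis="poly4")
        grid = np.linspace(79, 99, 50)
        fixed = m.predict_non_crossing(grid)
        assert np.all(np.diff(fixed, axis=0) >= 0)


class TestQrAic:
    def test_pure_function(self):
        rng = np.random.default_rng(41)
        t = rng.uniform(79, 99, 300)
        y = rng.uniform(0.1, 0.3, 300)
        m = cm.fit_quantile_curves(t, y, basis="linear")
        a = cm.qr_aic(m, t, y)
        b = cm.qr_aic(m, t, y)
        assert a == b

    def test_useless_column_raises_aic_on_null_data(self):
        # null (intercept + noise) truth: an extra basis column buys only a
        # spurious check-loss reduction, so on average the +2 parameter
        # penalty dominates and AIC rises by up to ~2 per level
        diffs = []
        for seed in range(50, 58):
            rng = np.random.default_rng(seed)
            t = rng.uniform(79, 99, 1000)
            y = 0.2 + 0.02 * rng.standard_normal(1000)
            levels = (0.25, 0.5, 0.75)
            m1 = cm.fit_quantile_curves(t, y, basis="linear", quantile_levels=levels)
            m2 = cm.fit_quantile_curves(t, y, basis="poly2", quantile_levels=levels)
            diffs += [m2.aic_per_level[q] - m1.aic_per_level[q] for q in levels]
        assert 0.0 < np.mean(diffs) < 3.0
        assert max(diffs) < 4.0

    def test_aic_improves_when_truth_is_quadratic(self):
        rng = np.random.default_rng(43)
        t = rng.uniform(79, 99, 2000)
        y = 0.2 + 0.01 * ((t - 89) / 5) ** 2 + 0.02 * rng.standard_normal(2000)
        lin = cm.fit_quantile_curves(t, y, basis="linear")
        quad = cm.fit_quantile_curves(t, y, basis="poly2")
        assert quad.aic < lin.aic

    def test_zero_loss_is_an_error(self):
        t = np.linspace(79, 99, 40)
        y = 0.1 + 0.002 * t  # exactly linear: the linear basis interpolates it
        with pytest.raises(cm.FitError):
            cm.fit_quantile_curves(t, y, basis="linear")


class TestSelectBestModel:
    @staticmethod
    def _stub(aic, edf, converged=True):
        m = model_from_curves("BCPEo", mu=0.2, sigma=0.4, nu=0.5)
        m.aic = aic
        m.total_edf = edf
        m.fit_meta["converged"] = converged
        return m

    def test_argmin_aic(self):
        models = [self._stub(-10, 5), self._stub(-12, 5), self._stub(-11, 5)]
        best, table = cm.select_best_model(models)
        assert best is models[1]
        assert list(table["selected"]) == [False, True, False]

    def test_tie_broken_by_edf_then_order(self):
        models = [self._stub(-10, 6), self._stub(-10, 4), self._stub(-10, 4)]
        best, _ = cm.select_best_model(models)
        assert best is models[1]

    def test_nonconverged_excluded(self):
        models = [self._stub(-99, 3, converged=False), self._stub(-10, 3)]
        best, table = cm.select_best_model(models)
        assert best is models[1]
        assert list(table["converged"]) == [False, True]

    def test_empty_list(self):
        with pytest.raises(ValueError):
            cm.select_best_model([])

    def test_family_screen_on_boxcox_truth_selects_boxcox(self):
        # truth is BCPEo with tau=2; either Box-Cox family is an acceptable
        # winner (they coincide at tau=2)
        t, y, _ = _simulate_truth(1200, seed=45)
        models = [cm.fit_lms(t, y, fam) for fam in dist.FAMILIES]
        best, _ = cm.select_best_model(models)
        assert best.family in ("BCCGo", "BCPEo")
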