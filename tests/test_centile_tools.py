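"""Centile curves, individual centiles, Z-scores and calibration."""

import numpy as np
import pytest
from scipy import stats

from placentile import centile_tools as ct

from conftest import model_from_curves


class TestCentileCurve:
    def test_curves_never_cross(self, truth_model):
        grid = np.arange(79.0, 100.0)
        lo = ct.centile_curve(truth_model, 0.03, grid)
        mid = ct.centile_curve(truth_model, 0.50, grid)
        hi = ct.centile_curve(truth_model, 0.97, grid)
        assert np.all(lo < mid) and np.all(mid < hi)

    def test_extrapolation_guard(self, truth_model):
        with pytest.raises(ValueError, match="outside fitted"):
            ct.centile_curve(truth_model, 0.5, [70.0])
        with pytest.warns(RuntimeWarning):
            vals = ct.centile_curve(truth_model, 0.5, [70.0], allow_extrapolation=True)
        assert np.isfinite(vals).all()

    def test_alpha_domain(self, truth_model):
        with pytest.raises(ValueError):
            ct.centile_curve(truth_model, 1.5, [89.0])

    def test_table_monotone_in_alpha(self, truth_model):
        table = ct.centile_table(truth_model)
        assert np.all(np.diff(table.values, axis=0) > 0)
        assert np.all(table.values > 0)
        frame = table.to_frame()
        assert list(frame.columns[:2]) == ["ga_days", "c1"]


class TestIndividualCentileAndZ:
    def test_inverse_identity_with_curve(self, truth_model):
        for alpha in (0.03, 0.25, 0.50, 0.90):
            for t in (80.0, 89.0, 98.0):
                y = float(ct.centile_curve(truth_model, alpha, [t])[0])
                got = ct.individual_centile(truth_model, t, y)
                assert got == pytest.approx(100 * alpha, abs=1e-6)

    def test_z_at_90th_centile(self, truth_model):
        y = float(ct.centile_curve(truth_model, 0.90, [89.0])[0])
        z = ct.z_score(truth_model, 89.0, y)
        assert float(z[0]) == pytest.approx(stats.norm.ppf(0.9), abs=1e-6)

    def test_z_monotone_in_y(self, truth_model):
        ys = np.array([0.05, 0.1, 0.2, 0.4])
        z = ct.z_score(truth_model, np.full(4, 89.0), ys)
        assert np.all(np.diff(z) > 0)

    def test_extreme_value_clamped_with_warning(self, truth_model):
        # far above the chart range the model CDF overflows to 1
        with pytest.warns(RuntimeWarning, match="clamped"):
            z = ct.z_score(truth_model, 89.0, 5.0)
        assert float(z[0]) == ct.Z_CLAMP

    def test_simulated_zscores_standard_normal(self, truth_model):
        rng = np.random.default_rng(61)
        t = rng.uniform(79, 99, 2500)
        y = ct.simulate_from_model(truth_model, t, seed=62)
        z = ct.z_score(truth_model, t, y)
        assert abs(z.mean()) < 0.05
        assert abs(z.std(ddof=1) - 1.0) < 0.05
        ks = stats.kstest(z, "norm")
        assert ks.pvalue > 0.01


class TestCalibration:
    def test_attainable_coverage_printed_count(self, truth_model):
        # n = 2547: the rank fraction nearest the 1st centile is 26/2547 = 1.02%
        rng = np.random.default_rng(63)
        t = rng.uniform(79, 99, 2547)
        y = ct.simulate_from_model(truth_model, t, seed=64)
        report = ct.calibration_table(truth_model, t, y)
        row = report.table[report.table["centile"] == 1.0].iloc[0]
        assert row["observed"] == 1.02
        assert round(100 * 26 / 2547, 2) == 1.02

    def test_perfect_model_calibrates(self, truth_model):
        rng = np.random.default_rng(65)
        t = rng.uniform(79, 99, 2500)
        y = ct.simulate_from_model(truth_model, t, seed=66)
        report = ct.calibration_table(truth_model, t, y)
        assert report.max_gap() < 2.0  # single-seed Monte-Carlo slack
        assert abs(report.z_diagnostics["mean"]) < 0.05
        assert abs(report.z_diagnostics["sd"] - 1.0) < 0.05

    def test_empty_data_rejected(self, truth_model):
        with pytest.raises(ValueError):
            ct.calibration_table(truth_model, np.array([]), np.array([]))

    def test_gap_definition(self, truth_model):
        rng = np.random.default_rng(67)
        t = rng.uniform(79, 99, 400)
        y = ct.simulate_from_model(truth_model, t, seed=68)
        rep = ct.calibration_table(truth_model, t, y)
        np.testing.assert_allclose(
            rep.table["gap"], np.abs(rep.table["predicted"] - rep.table["observed"]), atol=0.011
        )


@pytest.mark.parametrize("family,kw", [
    ("BCCGo", dict(mu=(0.16, 0.22), sigma=0.4, nu=0.5)),
    ("SEP3", dict(mu=(0.16, 0.22), sigma=(0.05, 0.07), nu=1.8, tau=1.5)),
])
def test_roundtrip_other_families(family, kw):
    model = model_from_curves(family, **kw)
    t = np.array([81.0, 90.0, 97.0])
    y = ct.centile_curve(model, 0.75, t)
    got = ct.individual_centile(model, t, y)
    np.testing.assert_allclose(got, 75.0, atol=1e-6)
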