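"""Correctness of the four response families against numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from placentile import distributions as dist
from placentile.distributions import DistributionParams

GRID = [
    DistributionParams("BCCGo", 0.2, 0.4, 0.5),
    DistributionParams("BCCGo", 0.2, 0.3, -1.0),
    DistributionParams("BCCGo", 0.15, 0.5, 0.0),
    DistributionParams("BCPEo", 0.2, 0.4, 0.3, 1.5),
    DistributionParams("BCPEo", 0.3, 0.5, -2.0, 4.0),
    DistributionParams("BCPEo", 0.1, 0.6, 3.0, 2.5),
    DistributionParams("SEP1", 0.2, 0.1, 3.0, 1.5),
    DistributionParams("SEP1", 0.2, 0.1, -2.0, 3.0),
    DistributionParams("SEP1", 0.25, 0.08, 0.0, 2.0),
    DistributionParams("SEP3", 0.2, 0.1, 2.0, 1.2),
    DistributionParams("SEP3", 0.2, 0.1, 0.5, 5.0),
    DistributionParams("SEP3", 0.3, 0.15, 1.0, 2.0),
]

ALPHAS = np.array([0.01, 0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97, 0.99])


def _support_lo(p):
    return 1e-12 if p.family in ("BCCGo", "BCPEo") else -np.inf


@pytest.mark.parametrize("params", GRID, ids=lambda p: f"{p.family}-nu{p.nu}-tau{p.tau}")
def test_pdf_integrates_to_one(params):
    total, err = integrate.quad(lambda y: dist.pdf(y, params), _support_lo(params), np.inf, limit=300)
    assert abs(total - 1.0) < 1e-6


@pytest.mark.parametrize("params", GRID, ids=lambda p: f"{p.family}-nu{p.nu}-tau{p.tau}")
def test_quantile_cdf_roundtrip_and_monotone(params):
    yq = dist.quantile(ALPHAS, params)
    assert np.all(np.diff(yq) > 0), "quantile must be strictly increasing in alpha"
    back = np.array([dist.cdf(float(v), params) for v in yq])
    assert np.max(np.abs(back - ALPHAS)) < 1e-8
    assert np.all(dist.pdf(yq, params) >= 0)


@pytest.mark.parametrize("params", GRID, ids=lambda p: f"{p.family}-nu{p.nu}-tau{p.tau}")
def test_cdf_consistent_with_pdf(params):
    # numeric derivative of the CDF matches the density on an interior grid
    y = dist.quantile(np.linspace(0.1, 0.9, 9), params)
    h = 1e-5 * (y[-1] - y[0])
    for yi in y:
        deriv = (dist.cdf(yi + h, params) - dist.cdf(yi - h, params)) / (2 * h)
        assert deriv == pytest.approx(dist.pdf(yi, params), rel=1e-4, abs=1e-8)


def test_bcpe_tau2_equals_bccg():
    y = np.linspace(0.01, 1.2, 80)
    for mu, sigma, nu in [(0.2, 0.4, 0.5), (0.3, 0.25, -0.8), (0.15, 0.5, 0.0)]:
        a = dist.pdf(y, DistributionParams("BCPEo", mu, sigma, nu, 2.0))
        b = dist.pdf(y, DistributionParams("BCCGo", mu, sigma, nu))
        np.testing.assert_allclose(a, b, rtol=1e-10, atol=1e-12)


@pytest.mark.parametrize(
    "params",
    [DistributionParams("SEP1", 0.2, 0.1, 0.0, 1.5), DistributionParams("SEP3", 0.2, 0.1, 1.0, 1.5)],
    ids=["SEP1-sym", "SEP3-sym"],
)
def test_sep_symmetric_at_symmetry_value(params):
    d = np.linspace(0.0, 0.3, 13)
    np.testing.assert_allclose(
        dist.pdf(params.mu + d, params), dist.pdf(params.mu - d, params), rtol=1e-12
    )


class TestBoxCoxTransform:
    def test_identity_at_mu(self):
        for nu in (-1.0, 0.0, 0.7, 2.0):
            p = DistributionParams("BCCGo", 0.2, 0.5, nu)
            assert dist.box_cox_z(0.2, p) == pytest.approx(0.0, abs=1e-12)

    def test_linear_case(self):
        p = DistributionParams("BCCGo", 0.2, 0.5, 1.0)
        assert dist.box_cox_z(0.3, p) == pytest.approx(1.0)

    def test_continuity_at_nu_zero(self):
        near = dist.box_cox_z(0.3, DistributionParams("BCCGo", 0.2, 0.5, 1e-9))
        at = dist.box_cox_z(0.3, DistributionParams("BCCGo", 0.2, 0.5, 0.0))
        assert near == pytest.approx(at, abs=1e-6)

    def test_rejects_nonpositive(self):
        p = DistributionParams("BCCGo", 0.2, 0.5, 1.0)
        with pytest.raises(ValueError):
            dist.box_cox_z(-0.1, p)
        with pytest.raises(ValueError):
            dist.box_cox_z(np.array([0.2, 0.0]), p)

    def test_sep_family_rejected(self):
        with pytest.raises(ValueError):
            dist.box_cox_z(0.3, DistributionParams("SEP3", 0.2, 0.1, 1.0, 2.0))


class TestGaussianClosedForms:
    """BCCGo with nu=1 is a truncated location-scale Gaussian."""

    def test_cdf_matches_truncated_gaussian(self):
        mu, sigma = 0.2, 0.3
        p = DistributionParams("BCCGo", mu, sigma, 1.0)
        y = np.linspace(0.02, 0.8, 25)
        z = (y / mu - 1.0) / sigma
        expected = (stats.norm.cdf(z) - stats.norm.cdf(-1 / sigma)) / stats.norm.cdf(1 / sigma)
        np.testing.assert_allclose(dist.cdf(y, p), expected, atol=1e-12)

    def test_median_is_mu_when_truncation_negligible(self):
        p = DistributionParams("BCCGo", 0.2, 0.1, 1.0)
        assert dist.truncation_mass(p) < 1e-6
        assert dist.cdf(0.2, p) == pytest.approx(0.5, abs=1e-6)
        assert dist.quantile(0.5, p) == pytest.approx(0.2, rel=1e-6)

    def test_upper_quantile_gaussian(self):
        p = DistributionParams("BCCGo", 1.0, 0.1, 1.0)
        got = dist.quantile(0.975, p)
        # truncation-corrected Gaussian: exact via the renormalized latent
        p_lat = 0.975 * stats.norm.cdf(10.0) + stats.norm.cdf(-10.0)
        assert got == pytest.approx(1.0 + 0.1 * stats.norm.ppf(p_lat), rel=1e-10)
        assert got == pytest.approx(1.0 + 0.1 * 1.959964, rel=1e-4)


class TestRvs:
    def test_same_seed_identical(self):
        p = DistributionParams("SEP3", 0.2, 0.1, 2.0, 1.5)
        a = dist.rvs(200, p, seed=42)
        b = dist.rvs(200, p, seed=42)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize(
        "params",
        [
            DistributionParams("BCPEo", 0.2, 0.4, 0.3, 1.5),
            DistributionParams("SEP1", 0.2, 0.1, 3.0, 1.5),
        ],
        ids=["BCPEo", "SEP1"],
    )
    def test_small_sample_quantiles(self, params):
        x = dist.rvs(4000, params, seed=5)
        q50 = dist.quantile(0.5, params)
        assert np.median(x) == pytest.approx(q50, rel=0.05)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            dist.rvs(0, GRID[0], seed=1)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"family": "BCCGo", "mu": -0.1, "sigma": 0.3, "nu": 1.0},
        {"family": "BCCGo", "mu": 0.2, "sigma": 0.0, "nu": 1.0},
        {"family": "BCPEo", "mu": 0.2, "sigma": 0.3, "nu": 1.0, "tau": -1.0},
        {"family": "SEP3", "mu": 0.2, "sigma": 0.3, "nu": -0.5, "tau": 2.0},
        {"family": "BCCGo", "mu": 0.2, "sigma": 0.3, "nu": np.inf},
        {"family": "NOPE", "mu": 0.2, "sigma": 0.3, "nu": 1.0},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        DistributionParams(**kwargs)


def test_alpha_domain_errors():
    p = GRID[0]
    for bad in (0.0, 1.0, -0.2, 1.5):
        with pytest.raises(ValueError):
            dist.quantile(bad, p)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    a1=st.floats(min_value=0.01, max_value=0.98),
    gap=st.floats(min_value=0.001, max_value=0.01),
    idx=st.integers(min_value=0, max_value=len(GRID) - 1),
)
def test_quantile_strictly_increasing_property(a1, gap, idx):
    params = GRID[idx]
    assert dist.quantile(a1, params) < dist.quantile(a1 + gap, params)
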