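"""Centile charts, individual centiles, Z-scores and calibration checks.

All operations consume a fitted chart model (:class:`FittedChartModel`):
centile curves are the age-conditional quantiles of the fitted response
distribution, an individual's centile is 100 times their model CDF value,
and the Z-score is the standard-normal transform of that CDF value.  The
calibration table compares, per target centile, the coverage the model
predicts on a dataset against the nearest attainable empirical rank
fraction — the chart-evaluation summary of "predicted vs observed" coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import distributions as dist
from .chart_models import FittedChartModel

#: the nine target centiles evaluated on the final charts
TARGET_CENTILES = (0.01, 0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97, 0.99)

#: Z-scores are clamped here when the model CDF over/underflows
Z_CLAMP = 8.0


@dataclass
class CentileTable:
    """Centile curve values on an age grid; one column per target centile."""

    t_grid: np.ndarray
    centiles: tuple
    values: np.ndarray  # shape (len(centiles), len(t_grid))
    extrapolated: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values.T,
            columns=[f"c{100 * a:g}" for a in self.centiles],
        )
        df.insert(0, "ga_days", self.t_grid)
        return df


@dataclass
class CalibrationReport:
    """Predicted vs attainable coverage per target centile, plus Z diagnostics."""

    table: pd.DataFrame  # columns: centile, predicted, observed, gap
    z_diagnostics: dict = field(default_factory=dict)

    def max_gap(self) -> float:
        return float(self.table["gap"].max())


def _check_range(model: FittedChartModel, t, allow_extrapolation):
    pc = model.param_curves
    t = np.asarray(t, float)
    outside = (t < pc.t_min) | (t > pc.t_max)
    if np.any(outside):
        if not allow_extrapolation:
            raise ValueError(
                f"age(s) outside fitted range [{pc.t_min:g}, {pc.t_max:g}] days; "
                "pass allow_extrapolation=True to evaluate anyway"
            )
        return True
    return False


def centile_curve(model: FittedChartModel, alpha: float, t_grid, allow_extrapolation=False):
    """The curve C_alpha(t): the fitted alpha-quantile across ages ``t_grid``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    flagged = _check_range(model, t_grid, allow_extrapolation)
    t_grid = np.atleast_1d(np.asarray(t_grid, float))
    mu, sigma, nu, tau = model.param_curves.values(t_grid)
    vals = dist.quantile_arrays(alpha, mu, sigma, nu, tau, model.family)
    if flagged:
        warnings.warn("centile_curve evaluated outside the fitted age range", RuntimeWarning)
    return vals


def centile_table(
    model: FittedChartModel,
    t_grid=None,
    centiles=TARGET_CENTILES,
    allow_extrapolation=False,
) -> CentileTable:
    """Full chart: all target centile curves on an age grid (default: whole-day grid)."""
    pc = model.param_curves
    if t_grid is None:
        t_grid = np.arange(np.ceil(pc.t_min), np.floor(pc.t_max) + 1)
    t_grid = np.atleast_1d(np.asarray(t_grid, float))
    flagged = _check_range(model, t_grid, allow_extrapolation)
    rows = [centile_curve(model, a, t_grid, allow_extrapolation) for a in centiles]
    return CentileTable(t_grid, tuple(centiles), np.vstack(rows), extrapolated=flagged)


def individual_centile(model: FittedChartModel, t, y, allow_extrapolation=False):
    """Centile (0..100 scale) of measurement ``y`` at age ``t`` under the model."""
    scalar = np.isscalar(t) and np.isscalar(y)
    _check_range(model, t, allow_extrapolation)
    t = np.atleast_1d(np.asarray(t, float))
    y = np.atleast_1d(np.asarray(y, float))
    if np.any(y <= 0):
        raise ValueError("measurements must be positive")
    mu, sigma, nu, tau = model.param_curves.values(t)
    p = dist.cdf_arrays(y, mu, sigma, nu, tau, model.family)
    out = 100.0 * p
    return float(out[0]) if scalar else out


def z_score(model: FittedChartModel, t, y, allow_extrapolation=False):
    """Standard-normal Z equivalent of the model CDF value at (t, y).

    CDF values that underflow to 0 or 1 are clamped to +-``Z_CLAMP`` with a
    warning rather than returning infinities.
    """
    cent = np.atleast_1d(individual_centile(model, t, y, allow_extrapolation)) / 100.0
    eps = stats.norm.cdf(-Z_CLAMP)
    clipped = (cent <= eps) | (cent >= 1 - eps)
    if np.any(clipped):
        warnings.warn(
            f"{int(clipped.sum())} extreme measurement(s): Z clamped to +-{Z_CLAMP:g}",
            RuntimeWarning,
        )
    z = stats.norm.ppf(np.clip(cent, eps, 1 - eps))
    z = np.where(cent <= eps, -Z_CLAMP, np.where(cent >= 1 - eps, Z_CLAMP, z))
    return z


def z_diagnostics(z) -> dict:
    """Moments and a normality statistic for a Z-score vector."""
    z = np.asarray(z, float)
    stat, p = stats.normaltest(z)
    return {
        "n": int(z.size),
        "mean": float(z.mean()),
        "sd": float(z.std(ddof=1)),
        "skewness": float(stats.skew(z)),
        "kurtosis": float(stats.kurtosis(z)),
        "normality_stat": float(stat),
        "normality_p": float(p),
    }


def calibration_table(
    model: FittedChartModel,
    t,
    y,
    target_centiles=TARGET_CENTILES,
    allow_extrapolation=False,
) -> CalibrationReport:
    """Predicted vs attainable observed coverage at each target centile.

    Predicted coverage at level alpha is the percentage of cases strictly
    below their age-specific fitted centile curve, 100*#{y_i < C_alpha(t_i)}/n
    (ties count as not-below; immaterial for continuous data but fixed for
    reproducibility).  The observed coverage is the percentage of cases
    strictly below the *empirical* alpha-quantile of the sample
    (linear-interpolation convention) — the attainable coverage of a
    perfectly calibrated chart on a sample of this size, which for a
    non-integer rank position equals 100*floor(1 + alpha*(n-1))/n.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if y.size == 0:
        raise ValueError("empty data")
    n = y.size
    rows = []
    zs = z_score(model, t, y, allow_extrapolation)
    for a in target_centiles:
        curve = centile_curve(model, a, t, allow_extrapolation)
        pred = 100.0 * np.sum(y < curve) / n
        obs = 100.0 * np.sum(y < np.quantile(y, a)) / n
        rows.append(
            {
                "centile": 100.0 * a,
                "predicted": round(pred, 2),
                "observed": round(obs, 2),
                "gap": round(abs(pred - obs), 2),
                "predicted_raw": pred,
            }
        )
    return CalibrationReport(pd.DataFrame(rows), z_diagnostics(zs))


def simulate_from_model(model: FittedChartModel, t, seed=None) -> np.ndarray:
    """Draw one response per age in ``t`` from the model's fitted distribution.

    The self-consistency workhorse: data simulated this way must calibrate
    perfectly (up to Monte-Carlo error) and must yield standard-normal
    Z-scores under the same model.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = np.atleast_1d(np.asarray(t, float))
    mu, sigma, nu, tau = model.param_curves.values(t)
    u = rng.uniform(size=t.size)
    return dist.quantile_arrays(u, mu, sigma, nu, tau, model.family)


def plot_chart(model: FittedChartModel, t, y, ax=None):
    """Render the chart: 50th solid, 25-75 band, 10/90 dashed, 3/97 dotted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    pc = model.param_curves
    grid = np.linspace(pc.t_min, pc.t_max, 200)
    curves = {a: centile_curve(model, a, grid) for a in (0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97)}
    ax.scatter(t, y, s=4, alpha=0.25, color="steelblue", linewidths=0)
    ax.fill_between(grid, curves[0.25], curves[0.75], color="gray", alpha=0.35, label="25th-75th")
    ax.plot(grid, curves[0.50], "k-", label="50th")
    for a in (0.10, 0.90):
        ax.plot(grid, curves[a], "k--", lw=1)
    for a in (0.03, 0.97):
        ax.plot(grid, curves[a], "k:", lw=1)
    ax.set_xlabel("Gestational age (days)")
    ax.set_ylabel("Measurement")
    ax.legend(loc="upper left", fontsize=8)
    return ax
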