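"""Spline design matrices and P-spline smoothness machinery.

Shared by the LMS fitter (penalized B-splines for the parameter curves) and
the quantile-regression comparator (its polynomial / natural-spline /
B-spline basis families).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize
from scipy.interpolate import BSpline

DEGREE = 3  # cubic throughout


def bspline_knots(t, n_basis: int, degree: int = DEGREE) -> np.ndarray:
    """Full (clamped) knot vector with interior knots at quantiles of ``t``.

    ``n_basis`` columns require ``n_basis - degree - 1`` interior knots.
    """
    t = np.asarray(t, float)
    n_interior = n_basis - degree - 1
    if n_interior < 0:
        raise ValueError(f"n_basis={n_basis} too small for degree {degree}")
    lo, hi = float(t.min()), float(t.max())
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(t, probs)
    else:
        interior = np.array([])
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def bspline_design(t, knots: np.ndarray, degree: int = DEGREE) -> np.ndarray:
    """Dense B-spline design matrix; endpoints clamped to the fitted range."""
    t = np.clip(np.asarray(t, float), knots[0], knots[-1])
    return BSpline.design_matrix(t, knots, degree, extrapolate=False).toarray()


def second_difference_penalty(n_basis: int) -> np.ndarray:
    """P-spline roughness penalty D2' D2 on the coefficient vector."""
    d = np.diff(np.eye(n_basis), n=2, axis=0)
    return d.T @ d


def edf_profile(a_mat: np.ndarray, pen: np.ndarray):
    """Eigenvalues e_j such that edf(lam) = sum_j 1/(1 + lam * e_j).

    ``a_mat`` is the (weighted) cross-product B'WB; the generalized
    eigendecomposition gives the whole effective-df profile in closed form.
    """
    jitter = 1e-10 * np.trace(a_mat) / a_mat.shape[0]
    c = linalg.cholesky(a_mat + jitter * np.eye(a_mat.shape[0]), lower=False)
    cinv = linalg.solve_triangular(c, np.eye(c.shape[0]), lower=False)
    m = cinv.T @ pen @ cinv
    e = linalg.eigvalsh((m + m.T) / 2.0)
    return np.clip(e, 0.0, None)


def lambda_for_edf(a_mat: np.ndarray, pen: np.ndarray, target_edf: float) -> float:
    """Smoothing parameter giving trace((B'WB + lam*P)^-1 B'WB) = target_edf.

    The attainable range is (nullity(P), n_basis); targets at or beyond the
    boundaries return the boundary smoother (lam = 0 or a very stiff lam).
    """
    e = edf_profile(a_mat, pen)

    def edf(lam):
        return float(np.sum(1.0 / (1.0 + lam * e)))

    if target_edf >= len(e) - 1e-8:
        return 0.0
    lo, hi = 1e-10, 1e12
    if edf(hi) > target_edf:  # target below what the penalty null space allows
        return hi
    return float(optimize.brentq(lambda L: edf(L) - target_edf, lo, hi, xtol=1e-12, rtol=1e-10))


def natural_spline_design(t, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond boundary knots), with intercept.

    Standard truncated-power construction: columns are 1, t, and
    N_k(t) = d_k(t) - d_{K-1}(t) for k = 1..K-2, where
    d_k(t) = ((t - xi_k)_+^3 - (t - xi_K)_+^3) / (xi_K - xi_k).
    """
    t = np.asarray(t, float)
    xi = np.asarray(knots, float)
    K = len(xi)
    if K < 3:
        raise ValueError("natural spline needs at least 3 knots")

    def d(k):
        return ((np.clip(t - xi[k], 0, None)) ** 3 - (np.clip(t - xi[K - 1], 0, None)) ** 3) / (
            xi[K - 1] - xi[k]
        )

    cols = [np.ones_like(t), t]
    dKm2 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dKm2)
    return np.column_stack(cols)


def polynomial_design(t, degree: int, center: float, scale: float) -> np.ndarray:
    """Raw polynomial basis on the standardized covariate, with intercept."""
    x = (np.asarray(t, float) - center) / scale
    return np.column_stack([x**p for p in range(degree + 1)])
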