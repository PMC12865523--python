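"""Gestational-age-conditional distribution models and their AIC comparison.

Two modeling paths are provided:

* the LMS/GAMLSS path — :func:`fit_lms` estimates smooth curves
  mu(t), sigma(t), nu(t), tau(t) for one of the skew response families by
  penalized maximum likelihood, cycling over the four parameter curves with
  a Fisher-scoring inner step (the Rigby-Stasinopoulos style backfit).
  Each curve is a cubic P-spline whose smoothing parameter is tuned to an
  effective-degrees-of-freedom (edf) target; edf targets are chosen on a
  grid by AIC with penalty multiplier ``k``.

* the quantile-regression comparator — :func:`fit_quantile_curves` fits
  per-quantile curves under an exact L1 solver (linear programming) or an
  L1-penalized ("lasso") check-loss solver, over linear, polynomial,
  natural-spline and B-spline basis families, with
  :func:`qr_aic` providing an asymmetric-Laplace AIC surrogate.

:func:`select_best_model` compares any mix of fitted candidates by AIC.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse, stats

from . import distributions as dist
from . import splines

log = logging.getLogger(__name__)

QR_BASES = ("linear", "poly2", "poly3", "poly4", "natural_spline", "b_spline")
QR_SOLVERS = ("exact_L1", "lasso_penalized")

#: default chart centiles, also the default QR quantile levels
DEFAULT_QUANTILES = (0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97)

DEFAULT_EDF_GRID = {
    "mu": (2, 3, 4, 5, 6),
    "sigma": (2, 3, 4),
    "nu": (1, 2),
    "tau": (1, 2),
}

_PARAM_ORDER = ("mu", "sigma", "nu", "tau")

_ETA_CLIP = 30.0


def _links_for(family: str) -> dict:
    # nu is the Box-Cox power (any real) for BC families and the Azzalini
    # skew (any real) for SEP1, but must stay positive for SEP3.
    nu_link = "log" if family == "SEP3" else "identity"
    return {"mu": "log", "sigma": "log", "nu": nu_link, "tau": "log"}


def _inv_link(eta, link):
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    return np.exp(eta) if link == "log" else eta


def _apply_link(value, link):
    return np.log(value) if link == "log" else value


# ---------------------------------------------------------------------------
# parameter curves
# ---------------------------------------------------------------------------


@dataclass
class ParamCurve:
    """One smooth parameter curve: eta(t) = design(t) @ coef, value = invlink."""

    name: str
    link: str
    kind: str  # "fixed" | "constant" | "linear" | "pspline"
    coef: np.ndarray
    knots: np.ndarray | None = None
    lam: float = 0.0
    edf: float = 0.0
    t_center: float = 0.0
    t_scale: float = 1.0

    def design(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        if self.kind in ("fixed", "constant"):
            return np.ones((t.size, 1))
        if self.kind == "linear":
            return np.column_stack([np.ones(t.size), (t - self.t_center) / self.t_scale])
        return splines.bspline_design(t, self.knots)

    def eta(self, t) -> np.ndarray:
        return self.design(t) @ self.coef

    def value(self, t) -> np.ndarray:
        return _inv_link(self.eta(t), self.link)


@dataclass
class ParamCurves:
    """The full set of age-varying parameter curves for one family."""

    family: str
    curves: dict  # name -> ParamCurve
    t_min: float
    t_max: float

    def values(self, t):
        """(mu, sigma, nu, tau) arrays at gestational ages ``t``."""
        return tuple(self.curves[p].value(t) for p in _PARAM_ORDER)

    def params_at(self, t: float) -> dist.DistributionParams:
        mu, sigma, nu, tau = (float(v[0]) for v in self.values([t]))
        return dist.DistributionParams(self.family, mu, sigma, nu, tau)


@dataclass
class FittedChartModel:
    """A fitted LMS chart model: curves plus fit quality bookkeeping."""

    param_curves: ParamCurves
    loglik: float
    total_edf: float
    aic: float
    fit_meta: dict = field(default_factory=dict)

    @property
    def family(self) -> str:
        return self.param_curves.family

    @property
    def converged(self) -> bool:
        return bool(self.fit_meta.get("converged", False))

    def params_at(self, t: float) -> dist.DistributionParams:
        return self.param_curves.params_at(t)

    def to_json(self) -> str:
        pc = self.param_curves
        doc = {
            "format": "placentile-chart-model",
            "version": 1,
            "family": pc.family,
            "t_range": [pc.t_min, pc.t_max],
            "curves": {
                name: {
                    "link": c.link,
                    "kind": c.kind,
                    "coef": list(map(float, np.atleast_1d(c.coef))),
                    "knots": None if c.knots is None else list(map(float, c.knots)),
                    "lambda": float(c.lam),
                    "edf": float(c.edf),
                    "t_center": float(c.t_center),
                    "t_scale": float(c.t_scale),
                }
                for name, c in pc.curves.items()
            },
            "loglik": float(self.loglik),
            "total_edf": float(self.total_edf),
            "aic": float(self.aic),
            "fit_meta": self.fit_meta,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FittedChartModel":
        doc = json.loads(text)
        if doc.get("format") != "placentile-chart-model":
            raise ValueError("not a chart-model document")
        curves = {
            name: ParamCurve(
                name=name,
                link=c["link"],
                kind=c["kind"],
                coef=np.asarray(c["coef"], float),
                knots=None if c["knots"] is None else np.asarray(c["knots"], float),
                lam=c["lambda"],
                edf=c["edf"],
                t_center=c["t_center"],
                t_scale=c["t_scale"],
            )
            for name, c in doc["curves"].items()
        }
        pc = ParamCurves(doc["family"], curves, doc["t_range"][0], doc["t_range"][1])
        return cls(pc, doc["loglik"], doc["total_edf"], doc["aic"], doc["fit_meta"])


# ---------------------------------------------------------------------------
# LMS fitting
# ---------------------------------------------------------------------------


class FitError(RuntimeError):
    pass


class _Term:
    """Design + penalty for one parameter curve at a given edf target."""

    def __init__(self, name, link, target_edf, t, fixed_eta=None):
        self.name = name
        self.link = link
        self.target = target_edf
        self.t_center = float(t.mean())
        self.t_scale = float(t.std() or 1.0)
        self.knots = None
        self.pen = None
        self.lam = 0.0
        if fixed_eta is not None:
            self.kind = "fixed"
            self.B = np.ones((t.size, 1))
            self.fixed_eta = fixed_eta
            self.edf = 0.0
        elif target_edf <= 1:
            self.kind = "constant"
            self.B = np.ones((t.size, 1))
            self.edf = 1.0
        elif target_edf == 2:
            self.kind = "linear"
            self.B = np.column_stack([np.ones(t.size), (t - self.t_center) / self.t_scale])
            self.edf = 2.0
        else:
            self.kind = "pspline"
            n_basis = int(target_edf) + 3
            self.knots = splines.bspline_knots(t, n_basis)
            self.B = splines.bspline_design(t, self.knots)
            self.pen = splines.second_difference_penalty(n_basis)
            self.edf = float(target_edf)  # refined at convergence

    @property
    def n_coef(self):
        return self.B.shape[1]


def _loglik_vec(y, family, etas, links):
    params = {p: _inv_link(etas[p], links[p]) for p in _PARAM_ORDER}
    with np.errstate(all="ignore"):
        ll = dist.logpdf_arrays(y, params["mu"], params["sigma"], params["nu"], params["tau"], family)
    return ll


def _initial_etas(t, y, family, terms, links):
    """Deterministic starting curves: smooth log-median, residual scale,
    no skew, Gaussian-type tails."""
    logy = np.log(y)
    init = {}
    # mu: (penalized) least-squares fit of log y on the mu design
    term = terms["mu"]
    B, pen = term.B, term.pen
    A = B.T @ B
    if pen is not None:
        lam = splines.lambda_for_edf(A, pen, term.target)
        coef = linalg.solve(A + lam * pen + 1e-10 * np.eye(A.shape[0]), B.T @ logy)
    else:
        coef = linalg.lstsq(B, logy)[0]
    eta_mu = B @ coef
    init["mu"] = coef
    resid = logy - eta_mu
    if family in ("BCCGo", "BCPEo"):
        scale0 = max(float(np.std(resid)), 1e-3)  # approx CV on the log scale
    else:
        scale0 = max(float(np.std(y - np.exp(eta_mu))), 1e-6)
    nu0 = {"BCCGo": 1.0, "BCPEo": 1.0, "SEP1": 0.0, "SEP3": 1.0}[family]
    start_vals = {"sigma": scale0, "nu": nu0, "tau": 2.0}
    for p in ("sigma", "nu", "tau"):
        term = terms[p]
        if term.kind == "fixed":
            init[p] = np.array([term.fixed_eta])
            continue
        coef = np.zeros(term.n_coef)
        eta0 = _apply_link(start_vals[p], links[p])
        if term.kind == "pspline":
            coef[:] = eta0  # B-spline basis sums to one
        else:
            coef[0] = eta0
        init[p] = coef
    return init


def _backfit(t, y, family, edf_targets, k, max_cycles, tol):
    """Run one penalized-likelihood backfit at fixed edf targets."""
    links = _links_for(family)
    n = y.size
    terms = {}
    for p in _PARAM_ORDER:
        fixed = None
        if family == "BCCGo" and p == "tau":
            fixed = np.log(2.0)
        terms[p] = _Term(p, links[p], edf_targets.get(p, 1), t, fixed_eta=fixed)
    coefs = _initial_etas(t, y, family, terms, links)
    for p in _PARAM_ORDER:
        if terms[p].kind == "fixed":
            coefs[p] = np.array([terms[p].fixed_eta])
    etas = {p: terms[p].B @ coefs[p] for p in _PARAM_ORDER}

    def penalty_term():
        s = 0.0
        for p in _PARAM_ORDER:
            tm = terms[p]
            if tm.kind == "pspline":
                s += 0.5 * tm.lam * float(coefs[p] @ tm.pen @ coefs[p])
        return s

    def objective():
        ll = _loglik_vec(y, family, etas, links)
        if not np.all(np.isfinite(ll)):
            return -np.inf
        return float(ll.sum()) - penalty_term()

    h = 1e-4
    obj = objective()
    if not np.isfinite(obj):
        raise FitError(f"{family}: initial parameter curves give non-finite likelihood")
    path = [obj]
    final_w = {}
    converged = False
    cycles_used = max_cycles
    for cycle in range(max_cycles):
        for p in _PARAM_ORDER:
            tm = terms[p]
            if tm.kind == "fixed":
                continue
            B = tm.B
            base = etas[p]
            l0 = _loglik_vec(y, family, etas, links)
            etas[p] = base + h
            lp = _loglik_vec(y, family, etas, links)
            etas[p] = base - h
            lm = _loglik_vec(y, family, etas, links)
            etas[p] = base
            u = (lp - lm) / (2 * h)
            w = -(lp - 2 * l0 + lm) / h**2
            bad = ~np.isfinite(u) | ~np.isfinite(w)
            u[bad] = 0.0
            w[bad] = 1e-6
            w = np.clip(w, 1e-6, 1e8)
            A = (B * w[:, None]).T @ B
            if tm.kind == "pspline":
                if cycle < 3:  # recalibrate smoothing to the edf target
                    tm.lam = splines.lambda_for_edf(A, tm.pen, tm.target)
                rhs = B.T @ u - tm.lam * (tm.pen @ coefs[p])
                lhs = A + tm.lam * tm.pen
            else:
                rhs = B.T @ u
                lhs = A
            try:
                delta = linalg.solve(lhs + 1e-10 * np.eye(lhs.shape[0]), rhs, assume_a="pos")
            except linalg.LinAlgError:
                continue
            alpha = 1.0
            improved = False
            for _ in range(12):
                cand = coefs[p] + alpha * delta
                etas[p] = B @ cand
                new_obj_coef = coefs[p]
                coefs[p] = cand
                new_obj = objective()
                if np.isfinite(new_obj) and new_obj >= obj - 1e-12:
                    obj = new_obj
                    improved = True
                    break
                coefs[p] = new_obj_coef
                etas[p] = B @ coefs[p]
                alpha /= 2.0
            final_w[p] = w
            if not improved:
                continue
        path.append(obj)
        if cycle >= 1 and abs(path[-1] - path[-2]) < tol:
            converged = True
            cycles_used = cycle + 1
            break

    # refine edf at the final weights
    total_edf = 0.0
    for p in _PARAM_ORDER:
        tm = terms[p]
        if tm.kind == "pspline" and p in final_w:
            B = tm.B
            A = (B * final_w[p][:, None]).T @ B
            e = splines.edf_profile(A, tm.pen)
            tm.edf = float(np.sum(1.0 / (1.0 + tm.lam * e)))
        total_edf += tm.edf

    loglik = float(_loglik_vec(y, family, etas, links).sum())
    aic = -2.0 * loglik + k * total_edf
    curves = {}
    for p in _PARAM_ORDER:
        tm = terms[p]
        curves[p] = ParamCurve(
            name=p,
            link=links[p],
            kind=tm.kind,
            coef=np.asarray(coefs[p], float),
            knots=tm.knots,
            lam=tm.lam,
            edf=tm.edf,
            t_center=tm.t_center,
            t_scale=tm.t_scale,
        )
    pc = ParamCurves(family, curves, float(t.min()), float(t.max()))
    meta = {
        "n": int(n),
        "k": float(k),
        "cycles": int(cycles_used),
        "converged": bool(converged),
        "edf_targets": {p: int(edf_targets.get(p, 1)) for p in _PARAM_ORDER},
        "loglik_path": [float(v) for v in path],
    }
    return FittedChartModel(pc, loglik, total_edf, aic, meta)


def fit_lms(
    t,
    y,
    family: str,
    edf_grid: dict | None = None,
    k: float = 2.0,
    max_cycles: int = 1000,
    tol: float = 1e-4,
) -> FittedChartModel:
    """Fit an LMS chart model by penalized maximum likelihood.

    Parameters
    ----------
    t, y
        Gestational age (days) and positive response values, equal length,
        at least 50 observations.
    family
        One of ``BCCGo``, ``BCPEo``, ``SEP1``, ``SEP3``.
    edf_grid
        Candidate effective-df targets per parameter, e.g.
        ``{"mu": (2,...,6), "sigma": (2,3,4), "nu": (1,2), "tau": (1,2)}``
        (the default).  edf 1 is a constant curve, 2 a linear trend, and
        >= 3 a penalized cubic B-spline tuned to that edf.  Smoothness is
        selected by coordinate search on the grid minimizing AIC with
        penalty multiplier ``k``.
    k
        AIC penalty per effective degree of freedom (default 2).
    max_cycles, tol
        Backfit cycle budget and the successive-cycle objective change
        below which the fit stops early.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be equal-length 1-D arrays")
    if t.size < 50:
        raise ValueError(f"need at least 50 observations, got {t.size}")
    if np.any(y <= 0):
        raise ValueError("response values must be positive")
    if np.ptp(y) == 0:
        raise FitError("degenerate data: constant response")
    if family not in dist.FAMILIES:
        raise ValueError(f"unknown family {family!r}")

    grid = dict(DEFAULT_EDF_GRID)
    if edf_grid:
        grid.update({p: tuple(np.atleast_1d(v)) for p, v in edf_grid.items()})
    if family == "BCCGo":
        grid["tau"] = (1,)  # tau fixed at 2; target ignored

    def closest(vals, want):
        vals = sorted(vals)
        return min(vals, key=lambda v: abs(v - want))

    current = {
        "mu": closest(grid["mu"], 3),
        "sigma": closest(grid["sigma"], 2),
        "nu": closest(grid["nu"], 1),
        "tau": closest(grid["tau"], 1),
    }
    cache = {}

    def fit_at(sel):
        key = tuple(sel[p] for p in _PARAM_ORDER)
        if key not in cache:
            cache[key] = _backfit(t, y, family, sel, k, max_cycles, tol)
        return cache[key]

    best = fit_at(current)
    for _sweep in range(2):
        changed = False
        for p in _PARAM_ORDER:
            if len(grid[p]) == 1:
                continue
            for v in grid[p]:
                if v == current[p]:
                    continue
                cand = fit_at({**current, p: v})
                if cand.aic < best.aic - 1e-9:
                    best, current = cand, {**current, p: v}
                    changed = True
        if not changed:
            break
    if not best.converged:
        warnings.warn(
            f"fit_lms({family}): backfit did not converge within {max_cycles} cycles",
            RuntimeWarning,
        )
    return best


# ---------------------------------------------------------------------------
# quantile regression comparator
# ---------------------------------------------------------------------------


@dataclass
class QuantileCurveModel:
    """Per-quantile regression curves under one basis and solver."""

    basis: str
    solver: str
    quantile_levels: tuple
    coef: dict  # level -> coefficient vector
    penalty: float
    t_center: float
    t_scale: float
    knots: np.ndarray | None
    loglik: float = np.nan  # asymmetric-Laplace surrogate, summed over levels
    aic: float = np.nan  # per-level mean (the scale comparable to one density fit)
    aic_sum: float = np.nan  # summed over quantile levels
    aic_per_level: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def total_edf(self) -> float:
        return float(sum(self._df(q) for q in self.quantile_levels))

    def _df(self, q) -> int:
        beta = self.coef[q]
        if self.solver == "lasso_penalized":
            return int(np.sum(np.abs(beta) > 1e-8))
        return int(beta.size)

    def design(self, t) -> np.ndarray:
        return _qr_design(np.atleast_1d(np.asarray(t, float)), self.basis, self.t_center, self.t_scale, self.knots)

    def predict(self, t, q=None) -> np.ndarray:
        """Fitted curve(s) at ages ``t``; all levels (rows) if q is None."""
        X = self.design(t)
        if q is not None:
            return X @ self.coef[q]
        return np.vstack([X @ self.coef[lev] for lev in self.quantile_levels])

    def predict_non_crossing(self, t) -> np.ndarray:
        """Raw per-level curves, rearranged monotonically across levels.

        Quantile-crossing repair by sorting the fitted values at each age;
        off by default in all outputs (raw curves are the primary result).
        """
        return np.sort(self.predict(t), axis=0)


def _qr_knots(t, basis):
    if basis == "natural_spline":
        return np.quantile(t, [0.0, 0.25, 0.5, 0.75, 1.0])
    if basis == "b_spline":
        return splines.bspline_knots(t, 6)
    return None


def _qr_design(t, basis, center, scale, knots):
    if basis == "linear":
        return splines.polynomial_design(t, 1, center, scale)
    if basis.startswith("poly"):
        return splines.polynomial_design(t, int(basis[4:]), center, scale)
    if basis == "natural_spline":
        return splines.natural_spline_design(t, knots)
    if basis == "b_spline":
        return splines.bspline_design(np.asarray(t, float), knots)
    raise ValueError(f"unknown basis {basis!r}; expected one of {QR_BASES}")


def _check_loss(r, q):
    return np.sum(r * (q - (r < 0)))


def _solve_check_loss_lp(X, y, q, penalty=0.0):
    """Exact minimizer of the check loss (+ L1 coefficient penalty) via LP.

    Variables [beta+, beta-, u, v] with X(beta+ - beta-) + u - v = y;
    objective q*sum(u) + (1-q)*sum(v) + penalty*sum(beta+ + beta-) over the
    non-intercept coefficients.
    """
    n, p = X.shape
    pen_vec = np.full(p, penalty)
    if penalty > 0:
        pen_vec[0] = 0.0  # intercept unpenalized
    c = np.concatenate([pen_vec, pen_vec, np.full(n, q), np.full(n, 1.0 - q)])
    A = sparse.hstack([sparse.csc_matrix(X), -sparse.csc_matrix(X), sparse.eye(n), -sparse.eye(n)])
    res = optimize.linprog(c, A_eq=A.tocsc(), b_eq=y, bounds=(0, None), method="highs")
    if not res.success:
        raise FitError(f"LP solver failed for quantile {q}: {res.message}")
    z = res.x
    return z[:p] - z[p : 2 * p]


def fit_quantile_curves(
    t,
    y,
    basis: str = "b_spline",
    solver: str = "exact_L1",
    quantile_levels=DEFAULT_QUANTILES,
    penalty: float = 1.0,
) -> QuantileCurveModel:
    """Fit per-quantile curves of ``y`` against gestational age ``t``.

    ``solver="exact_L1"`` computes the exact check-loss minimizer by linear
    programming; ``solver="lasso_penalized"`` adds an L1 penalty of weight
    ``penalty`` on the non-intercept coefficients (also solved exactly, the
    penalty being LP-representable).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if solver not in QR_SOLVERS:
        raise ValueError(f"unknown solver {solver!r}; expected one of {QR_SOLVERS}")
    center, scale = float(t.mean()), float(t.std() or 1.0)
    knots = _qr_knots(t, basis)
    X = _qr_design(t, basis, center, scale, knots)
    if t.size <= X.shape[1]:
        raise ValueError(f"need more observations than basis dimension ({X.shape[1]})")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(f"singular design for basis {basis!r}")
    lam = penalty if solver == "lasso_penalized" else 0.0
    coef = {}
    for q in quantile_levels:
        coef[q] = _solve_check_loss_lp(X, y, q, lam)
    model = QuantileCurveModel(
        basis=basis,
        solver=solver,
        quantile_levels=tuple(quantile_levels),
        coef=coef,
        penalty=lam,
        t_center=center,
        t_scale=scale,
        knots=knots,
    )
    table = qr_aic(model, t, y)
    # the summed surrogate grows with the number of levels; the per-level
    # mean is the scale comparable against a single-distribution AIC, so it
    # is the headline value used for selection (both are retained)
    model.aic = float(table["mean_aic"])
    model.aic_sum = float(table["total_aic"])
    model.loglik = float(table["total_loglik"])
    model.aic_per_level = {q: float(a) for q, a in table["aic"].items()}
    return model


def qr_aic(model: QuantileCurveModel, t, y) -> dict:
    """Asymmetric-Laplace AIC surrogate for a fitted quantile-curve model.

    Per level q with residuals r_i and p_q coefficients:
    logLik_q = n*(log(q(1-q)) - 1 - log(mean check loss)),
    AIC_q = 2*p_q - 2*logLik_q.  Returns per-level values and their sums
    (both are reported since either convention may be wanted downstream).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = y.size
    out_ll, out_aic = {}, {}
    for q in model.quantile_levels:
        r = y - model.predict(t, q)
        loss = _check_loss(r, q) / n
        if loss <= 1e-12 * max(1.0, float(np.mean(np.abs(y)))):
            raise FitError(f"zero residual check loss at quantile {q} (exact interpolation)")
        ll = n * (np.log(q * (1 - q)) - 1.0 - np.log(loss))
        out_ll[q] = float(ll)
        out_aic[q] = float(2.0 * model._df(q) - 2.0 * ll)
    return {
        "loglik": out_ll,
        "aic": out_aic,
        "total_loglik": float(sum(out_ll.values())),
        "total_aic": float(sum(out_aic.values())),
        "mean_aic": float(np.mean(list(out_aic.values()))),
    }


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def _label(m) -> str:
    if isinstance(m, FittedChartModel):
        return f"LMS/{m.family}"
    return f"QR/{m.basis}/{m.solver}"


def select_best_model(candidates):
    """Pick the minimum-AIC model from a mixed LMS/QR candidate list.

    Non-converged candidates are excluded (with a warning).  Ties on AIC go
    to the candidate with fewer effective df, then to declaration order.
    Returns ``(best_model, comparison_table)`` where the table is a
    DataFrame with one row per candidate.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    rows = []
    eligible = []
    for i, m in enumerate(candidates):
        conv = bool(getattr(m, "converged", True))
        edf = float(m.total_edf)
        rows.append(
            {
                "model": _label(m),
                "aic": float(m.aic),
                "edf": edf,
                "converged": conv,
            }
        )
        if conv:
            eligible.append((float(m.aic), edf, i, m))
        else:
            log.warning("select_best_model: excluding non-converged candidate %s", _label(m))
    if not eligible:
        raise FitError("no converged candidate to select from")
    eligible.sort(key=lambda x: (round(x[0], 12), x[1], x[2]))
    best = eligible[0][3]
    table = pd.DataFrame(rows)
    table["selected"] = [m is best for m in candidates]
    return best, table
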