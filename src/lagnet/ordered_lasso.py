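"""Penalized lagged regression with monotone coefficient-magnitude constraints.

This module solves, for one target gene, the optimization

    min_w  1/2 * sum_t ( y(t) - sum_{j,k} w[j,k] * x_j(t - k*dt) )^2
           + lambda * sum_j pen_j * sum_k |w[j,k]|
    s.t.   |w[j,1]| >= |w[j,2]| >= ... >= |w[j,l_max]|   for every predictor j,

i.e. an l1-penalized autoregression in which the influence of each predictor
is forced to decay (in magnitude) with the lag.  The per-predictor penalty
multipliers ``pen_j`` allow prior edges and prior non-edges to be regularized
separately; with uniform multipliers the problem is the plain de novo form.

The solver splits every coefficient into non-negative positive and negative
parts, each constrained to be non-increasing across lags, and runs a monotone
accelerated proximal-gradient iteration.  The proximal operator of the penalty
plus the order constraint is a shifted isotonic projection (pool-adjacent-
violators) clipped at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

NONZERO_TOL = 1e-10
"""Coefficients with absolute value at or below this (after back-scaling to the
original units) are treated as exactly zero when deciding edge membership."""


class ConvergenceError(RuntimeError):
    """Raised when the proximal-gradient iteration exhausts its iteration cap.

    Carries the last iterate (``last_coefficients``) and the recorded objective
    history (``objective_history``) for diagnosis.
    """

    def __init__(self, message, last_coefficients=None, objective_history=None):
        super().__init__(message)
        self.last_coefficients = last_coefficients
        self.objective_history = objective_history


def monotone_nonincreasing_projection(v):
    """Euclidean projection of ``v`` onto the cone of non-increasing sequences.

    This is classical isotonic regression with non-increasing order, computed
    by pool-adjacent-violators: scanning left to right, any block whose mean
    exceeds its predecessor's would violate the order were it kept separate,
    so the two blocks are pooled and replaced by their joint mean.

    Parameters
    ----------
    v : array-like, shape (m,)
        Finite values, m >= 1.

    Returns
    -------
    ndarray, shape (m,)
        The closest (in squared error) non-increasing sequence.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValueError("input must be a 1-D vector of length >= 1")
    if not np.all(np.isfinite(v)):
        raise ValueError("input contains non-finite values")
    means: list[float] = []
    counts: list[int] = []
    for x in v:
        cm, cc = float(x), 1
        # pooling condition for non-increasing order: a later block may not
        # have a larger mean than an earlier one
        while means and means[-1] < cm:
            cm = (cm * cc + means[-1] * counts[-1]) / (cc + counts[-1])
            cc += counts[-1]
            means.pop()
            counts.pop()
        means.append(cm)
        counts.append(cc)
    return np.repeat(means, counts)


@dataclass(frozen=True)
class LaggedProblem:
    """Design matrix for one target gene's lagged expression model.

    Columns are grouped by predictor: predictor ``j`` occupies the ``l_max``
    consecutive columns ``j*l_max ... (j+1)*l_max - 1``, ordered by increasing
    lag (k = 1 ... l_max).  Rows are usable time points; rows coming from
    different replicate series are stacked but never mix observations across a
    series boundary (the caller guarantees this during construction).
    """

    design: np.ndarray
    response: np.ndarray
    n_predictors: int
    l_max: int

    def __post_init__(self):
        X = np.asarray(self.design, dtype=float)
        y = np.asarray(self.response, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise ValueError("design and response shapes are inconsistent")
        if X.shape[0] < 1:
            raise ValueError("problem must have at least one row")
        if self.l_max < 1 or self.n_predictors < 1:
            raise ValueError("n_predictors and l_max must be positive")
        if X.shape[1] != self.n_predictors * self.l_max:
            raise ValueError(
                f"expected {self.n_predictors * self.l_max} columns "
                f"(p*l_max), got {X.shape[1]}"
            )
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("design/response contain non-finite values")
        object.__setattr__(self, "design", X)
        object.__setattr__(self, "response", y)

    def group_map(self):
        """Return (predictor index, lag) for every column, lag in 1..l_max."""
        return [
            (col // self.l_max, col % self.l_max + 1)
            for col in range(self.design.shape[1])
        ]


@dataclass(frozen=True)
class PenaltyWeights:
    """Per-predictor penalty multipliers (uniform for de novo inference)."""

    multipliers: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.multipliers, dtype=float)
        if m.ndim != 1 or np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("penalty multipliers must be non-negative finite")
        object.__setattr__(self, "multipliers", m)

    @classmethod
    def uniform(cls, n_predictors):
        return cls(np.ones(n_predictors))


@dataclass
class CoefficientTensor:
    """Fitted coefficients for one target gene.

    ``w[j, k-1]`` multiplies predictor ``j`` at lag ``k`` in the original data
    units; ``w_std`` holds the same coefficients on the standardized scale the
    solver works in (columns centered, each predictor group scaled by its
    pooled standard deviation — a shared scale per group keeps the magnitude
    ordering identical on both scales).
    """

    w: np.ndarray
    intercept: float
    w_std: np.ndarray
    objective: float
    objective_history: np.ndarray = field(repr=False)
    n_iter: int = 0
    converged: bool = True

    def nonzero_mask(self, tol=NONZERO_TOL):
        return np.abs(self.w) > tol

    def monotonicity_violation(self):
        """Largest increase |w[j,k+1]| - |w[j,k]| across all groups (<= 0 when
        the lag-decay constraint holds exactly)."""
        a = np.abs(self.w_std)
        if a.shape[1] < 2:
            return 0.0
        return float(np.max(np.diff(a, axis=1)))


def _standardize(problem):
    """Center columns/response; scale each predictor group by its pooled SD.

    Returns (Xc, yc, col_means, group_scales, y_mean).  A shared scale per
    group (rather than per column) means the monotone magnitude ordering is
    preserved when mapping coefficients back to the original units.
    """
    X, y = problem.design, problem.response
    p, l = problem.n_predictors, problem.l_max
    col_means = X.mean(axis=0)
    Xc = X - col_means
    pooled = Xc.reshape(X.shape[0], p, l)
    group_sd = np.sqrt(np.mean(pooled**2, axis=(0, 2)))  # pooled over lags
    group_sd = np.where(group_sd > 0, group_sd, 1.0)
    scales = np.repeat(group_sd, l)
    Xc = Xc / scales
    y_mean = y.mean()
    yc = y - y_mean
    return Xc, yc, col_means, scales, y_mean


def _column_penalties(problem, weights, lam):
    if weights is None:
        weights = PenaltyWeights.uniform(problem.n_predictors)
    elif not isinstance(weights, PenaltyWeights):
        weights = PenaltyWeights(np.asarray(weights, dtype=float))
    if weights.multipliers.shape[0] != problem.n_predictors:
        raise ValueError("one penalty multiplier per predictor is required")
    return np.repeat(weights.multipliers * lam, problem.l_max), weights


def _prox(v, thresh, p, l, monotone):
    """Prox of the linear penalty over the non-negative (and, if ``monotone``,
    non-increasing-by-lag) cone, applied to one sign part."""
    z = v - thresh
    if not monotone or l == 1:
        return np.maximum(z, 0.0)
    out = np.empty_like(z)
    for j in range(p):
        sl = slice(j * l, (j + 1) * l)
        out[sl] = np.maximum(monotone_nonincreasing_projection(z[sl]), 0.0)
    return out


def fit_time_lagged_ordered_lasso(
    problem,
    lam,
    weights=None,
    monotone=True,
    max_iter=10000,
    tol=1e-8,
    w_std_init=None,
):
    """Fit the lag-monotone l1-penalized autoregression for one target.

    Parameters
    ----------
    problem : LaggedProblem
    lam : float
        Global penalty level, >= 0 (scaled further by per-predictor weights).
    weights : PenaltyWeights or array, optional
        Per-predictor multipliers; uniform if omitted.
    monotone : bool
        With ``False`` the order constraint is dropped and the problem is the
        ordinary lasso on lagged covariates (the Lasso-Granger model).
    w_std_init : ndarray (p, l_max), optional
        Warm start on the standardized scale (used along a penalty path).

    Returns
    -------
    CoefficientTensor

    Raises
    ------
    ConvergenceError
        If the relative objective change has not fallen below ``tol`` within
        ``max_iter`` iterations.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    p, l = problem.n_predictors, problem.l_max
    Xc, yc, col_means, scales, y_mean = _standardize(problem)
    colpen, _ = _column_penalties(problem, weights, lam)
    m = p * l

    def finish(u_p, u_n, history, n_iter):
        w_std = (u_p - u_n).reshape(p, l)
        r = yc - Xc @ (u_p - u_n)
        # report the objective of Eq-form (penalty on |w|); at complementarity
        # of the split parts it coincides with the solver's internal objective
        final = 0.5 * float(r @ r) + float(colpen @ np.abs(u_p - u_n))
        w = w_std / scales.reshape(p, l)
        intercept = y_mean - float(w_std.reshape(-1) @ (col_means / scales))
        return CoefficientTensor(
            w=w,
            intercept=intercept,
            w_std=w_std.copy(),
            objective=final,
            objective_history=np.asarray(history),
            n_iter=n_iter,
            converged=True,
        )

    def split_objective(u_p, u_n):
        r = yc - Xc @ (u_p - u_n)
        return 0.5 * float(r @ r) + float(colpen @ (u_p + u_n))

    # trivial cases: nothing to explain or nothing to fit with
    lip = 2.0 * np.linalg.norm(Xc, 2) ** 2 if m else 0.0
    if lip == 0.0 or not np.any(yc):
        z = np.zeros(m)
        return finish(z, z, [split_objective(z, z)], 0)

    if w_std_init is not None:
        w0 = np.asarray(w_std_init, dtype=float).reshape(-1)
        if w0.shape[0] != m:
            raise ValueError("warm start has wrong shape")
        x_p = np.maximum(w0, 0.0)
        x_n = np.maximum(-w0, 0.0)
    else:
        x_p = np.zeros(m)
        x_n = np.zeros(m)

    step = 1.0 / lip
    z_p, z_n = x_p.copy(), x_n.copy()  # extrapolated point
    t = 1.0
    at_x = True  # whether the extrapolated point currently equals the iterate
    f_x = split_objective(x_p, x_n)
    history = [f_x]
    for it in range(1, max_iter + 1):
        r = yc - Xc @ (z_p - z_n)
        g = Xc.T @ r  # gradient wrt w is -g; wrt (u+, u-) it is (-g, +g)
        u_p = _prox(z_p + step * g, step * colpen, p, l, monotone)
        u_n = _prox(z_n - step * g, step * colpen, p, l, monotone)
        f_u = split_objective(u_p, u_n)
        if f_u <= f_x:
            x_prev_p, x_prev_n = x_p, x_n
            x_p, x_n, f_prev, f_x = u_p, u_n, f_x, f_u
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            # momentum runs through the proximal point (keeps the accelerated
            # rate) while the accepted iterate keeps the objective monotone
            z_p = u_p + ((t - 1.0) / t_new) * (x_p - x_prev_p)
            z_n = u_n + ((t - 1.0) / t_new) * (x_n - x_prev_n)
            t = t_new
            at_x = False
            history.append(f_x)
            if abs(f_prev - f_x) <= tol * max(1.0, abs(f_x)):
                return finish(x_p, x_n, history, it)
        elif at_x:
            # a plain proximal-gradient step from the iterate itself cannot
            # increase the objective at step 1/L, so failing to decrease it
            # means progress is below float resolution: stationary
            return finish(x_p, x_n, history, it)
        else:
            # extrapolation overshot: restart momentum at the current iterate
            z_p, z_n = x_p.copy(), x_n.copy()
            t = 1.0
            at_x = True
            history.append(f_x)
    raise ConvergenceError(
        f"no convergence within {max_iter} iterations "
        f"(last objective {history[-1]:.6g})",
        last_coefficients=(x_p - x_n).reshape(p, l),
        objective_history=np.asarray(history),
    )


def lambda_max(problem, weights=None, monotone=True):
    """Smallest penalty level at which the fitted model is identically zero.

    For the order-constrained problem the zero solution is optimal iff, for
    every predictor group, every prefix-mean of the (standardized)
    column-response inner products is below ``lambda * pen_j`` in absolute
    value; the extreme rays of the non-negative non-increasing cone are
    prefix indicator vectors, which makes this criterion exact.  Without the
    constraint the criterion is the usual per-column maximum.
    """
    colpen, weights = _column_penalties(problem, weights, 1.0)
    if np.any(weights.multipliers <= 0):
        raise ValueError("lambda_max requires strictly positive multipliers")
    Xc, yc, *_ = _standardize(problem)
    if not np.any(yc):
        warnings.warn("response has zero variance; lambda_max is 0")
        return 0.0
    c = Xc.T @ yc
    p, l = problem.n_predictors, problem.l_max
    crit = 0.0
    for j in range(p):
        cj = c[j * l : (j + 1) * l]
        if monotone:
            prefix = np.cumsum(cj) / np.arange(1, l + 1)
            group_crit = float(np.max(np.abs(prefix)))
        else:
            group_crit = float(np.max(np.abs(cj)))
        crit = max(crit, group_crit / weights.multipliers[j])
    return crit
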