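"""Per-gene lagged regression problems and de novo network inference.

A gene regulatory network is estimated by fitting, for every target gene i,
an autoregression of x_i(t) on the lagged expression x_j(t - k*dt) of all
genes j (including gene i itself) for lags k = 1..l_max, penalized with the
lag-monotone l1 penalty.  An edge j -> i is predicted whenever any lag
coefficient of j in target i's model is non-zero; because coefficient
magnitudes are non-increasing in the lag, this reduces to checking the first
lag.  Ranking edges by the penalty level at which they first enter the model
along a descending lambda path gives the merged-path ROC ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ordered_lasso import (
    NONZERO_TOL,
    LaggedProblem,
    fit_time_lagged_ordered_lasso,
    lambda_max,
)


class InvalidConfigurationError(ValueError):
    """A dataset / parameter combination that cannot be fit."""


@dataclass(frozen=True)
class ExpressionDataset:
    """Multi-series time-course expression data.

    Parameters
    ----------
    gene_names : sequence of str
    series : list of ndarray, each (p genes, T_s time points)
        Replicate time series, all with the same gene order, uniformly
        sampled at interval ``dt`` (arbitrary expression units).
    dt : float
        Sampling interval, > 0.
    """

    gene_names: tuple
    series: tuple
    dt: float = 1.0

    def __post_init__(self):
        names = tuple(str(g) for g in self.gene_names)
        mats = tuple(np.asarray(s, dtype=float) for s in self.series)
        if len(names) == 0 or len(mats) == 0:
            raise ValueError("dataset needs at least one gene and one series")
        p = len(names)
        for idx, s in enumerate(mats):
            if s.ndim != 2 or s.shape[0] != p:
                raise ValueError(
                    f"series {idx} has shape {s.shape}; expected ({p}, T)"
                )
            if s.shape[1] < 2:
                raise ValueError(f"series {idx} has fewer than 2 time points")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"series {idx} contains non-finite values")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError("dt must be positive")
        object.__setattr__(self, "gene_names", names)
        object.__setattr__(self, "series", mats)

    @property
    def n_genes(self):
        return len(self.gene_names)

    @property
    def n_series(self):
        return len(self.series)

    def gene_index(self, name):
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"unknown gene {name!r}") from None


@dataclass(frozen=True)
class DirectedNetwork:
    """Gene-level directed edge set; edges are (source index, target index)."""

    gene_names: tuple
    edges: frozenset

    def __post_init__(self):
        names = tuple(str(g) for g in self.gene_names)
        edges = frozenset((int(j), int(i)) for j, i in self.edges)
        p = len(names)
        for j, i in edges:
            if not (0 <= j < p and 0 <= i < p):
                raise ValueError(f"edge ({j}, {i}) has out-of-range endpoints")
        object.__setattr__(self, "gene_names", names)
        object.__setattr__(self, "edges", edges)

    def named_edges(self):
        return sorted(
            (self.gene_names[j], self.gene_names[i]) for j, i in self.edges
        )


@dataclass(frozen=True)
class RegularizationPath:
    """Edge entry values along a descending penalty grid.

    ``entry_value[(j, i)]`` is the largest grid lambda at which the edge
    j -> i is active; pairs that never enter map to ``None``.  Thresholding
    at any grid value yields nested predicted edge sets as lambda decreases.
    """

    gene_names: tuple
    lambdas: np.ndarray
    entry_value: dict

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.ndim != 1 or lam.size < 2:
            raise ValueError("lambda grid must be 1-D with length >= 2")
        if np.any(lam <= 0) or np.any(np.diff(lam) >= 0):
            raise ValueError("lambda grid must be strictly decreasing, positive")
        grid = set(lam.tolist())
        for pair, val in self.entry_value.items():
            if val is not None and val not in grid:
                raise ValueError(f"entry value for {pair} is not on the grid")
        object.__setattr__(self, "lambdas", lam)

    def network_at(self, lam):
        """Edges whose entry value is >= ``lam`` (the merged prediction)."""
        edges = {
            pair
            for pair, val in self.entry_value.items()
            if val is not None and val >= lam
        }
        return DirectedNetwork(self.gene_names, frozenset(edges))


def build_lagged_problem(data, target, l_max):
    """Assemble the lagged design for one target gene.

    One row per usable time point per series (the first ``l_max`` points of
    each series only serve as lagged covariates); rows never span a boundary
    between two replicate series.  Columns are x_j(t - k*dt) for every gene j
    — including the target itself — grouped by predictor, lag-major within a
    group.
    """
    if not isinstance(target, (int, np.integer)):
        target = data.gene_index(target)
    if not 0 <= target < data.n_genes:
        raise ValueError(f"target index {target} out of range")
    if l_max < 1:
        raise ValueError("l_max must be a positive integer")
    p = data.n_genes
    rows = []
    responses = []
    for s_idx, s in enumerate(data.series):
        T = s.shape[1]
        if T < l_max + 1:
            raise InvalidConfigurationError(
                f"series {s_idx} has {T} time points; l_max={l_max} needs "
                f"at least {l_max + 1}"
            )
        for t in range(l_max, T):
            # column layout: predictor-major, lag k = 1..l_max within a group
            row = np.empty(p * l_max)
            for j in range(p):
                for k in range(1, l_max + 1):
                    row[j * l_max + (k - 1)] = s[j, t - k]
            rows.append(row)
            responses.append(s[target, t])
    return LaggedProblem(
        design=np.asarray(rows),
        response=np.asarray(responses),
        n_predictors=p,
        l_max=l_max,
    )


def dataset_lambda_max(data, l_max, monotone=True):
    """Largest per-target critical penalty across all targets."""
    return max(
        lambda_max(build_lagged_problem(data, i, l_max), monotone=monotone)
        for i in range(data.n_genes)
    )


def default_lambda_grid(data, l_max, n_lambdas=100, ratio=1e-4, monotone=True):
    """Shared descending log-spaced grid from the dataset-wide critical
    penalty down to ``ratio`` times it (a common grid makes entry values
    comparable across target genes)."""
    top = dataset_lambda_max(data, l_max, monotone=monotone)
    if top <= 0:
        raise InvalidConfigurationError(
            "all responses have zero variance; no meaningful lambda grid"
        )
    return np.geomspace(top, top * ratio, n_lambdas)


def _fit_path_for_target(problem, grid, weights=None, monotone=True, target=None):
    """Warm-started coefficient path, large to small lambda.

    Returns an array (len(grid), p, l_max) of back-scaled coefficients.
    """
    coefs = np.empty((len(grid), problem.n_predictors, problem.l_max))
    w_start = None
    for g, lam in enumerate(grid):
        try:
            fit = fit_time_lagged_ordered_lasso(
                problem, lam, weights=weights, monotone=monotone,
                w_std_init=w_start,
            )
        except Exception as exc:
            label = f" (target {target})" if target is not None else ""
            raise type(exc)(f"{exc}{label}") from exc
        coefs[g] = fit.w
        w_start = fit.w_std
    return coefs


def _entries_from_active(active, grid):
    """Merge an activity profile along the descending grid into entry values.

    ``active`` is boolean, shape (n_lambdas,); the entry value is the largest
    grid lambda at which the edge is active.  An edge that leaves and
    re-enters at smaller lambda keeps its first (largest) entry, which makes
    thresholded edge sets nested as lambda decreases.
    """
    idx = np.flatnonzero(active)
    return float(grid[idx[0]]) if idx.size else None


def edge_entry_path(data, l_max, lambda_grid=None, include_self=False,
                    monotone=True):
    """Entry value of every directed pair along a descending lambda grid.

    Under the lag-monotone constraint an edge is active iff its first-lag
    coefficient is non-zero; without the constraint (``monotone=False``) all
    lags are checked.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(data, l_max, monotone=monotone)
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise InvalidConfigurationError("lambda grid is empty")
    if np.any(grid <= 0) or (grid.size > 1 and np.any(np.diff(grid) >= 0)):
        raise InvalidConfigurationError(
            "lambda grid must be strictly decreasing and positive"
        )
    p = data.n_genes
    entry = {}
    for i in range(p):
        problem = build_lagged_problem(data, i, l_max)
        coefs = _fit_path_for_target(problem, grid, monotone=monotone, target=i)
        for j in range(p):
            if j == i and not include_self:
                continue
            if monotone:
                active = np.abs(coefs[:, j, 0]) > NONZERO_TOL
            else:
                active = np.any(np.abs(coefs[:, j, :]) > NONZERO_TOL, axis=1)
            entry[(j, i)] = _entries_from_active(active, grid)
    return RegularizationPath(data.gene_names, grid, entry)


def infer_network_denovo(data, l_max, lam, include_self=False):
    """De novo network at a single penalty level.

    Fits the lag-monotone penalized autoregression for every target gene and
    predicts the edge j -> i iff the first-lag coefficient of predictor j is
    non-zero in target i's model.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    edges = set()
    for i in range(data.n_genes):
        problem = build_lagged_problem(data, i, l_max)
        try:
            fit = fit_time_lagged_ordered_lasso(problem, lam)
        except Exception as exc:
            raise type(exc)(
                f"{exc} (target {data.gene_names[i]})"
            ) from exc
        for j in range(data.n_genes):
            if j == i and not include_self:
                continue
            if abs(fit.w[j, 0]) > NONZERO_TOL:
                edges.add((j, i))
    return DirectedNetwork(data.gene_names, frozenset(edges))
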