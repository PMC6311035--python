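"""Semi-supervised network refinement against a prior edge set.

A prior network E splits each target's predictors into prior regulators
(penalized at lambda_edge) and prior non-regulators (penalized at
lambda_non_edge).  With lambda_edge < lambda_non_edge the known regulators
absorb most of the explainable variance, and the fit reports

* novel edges  — pairs outside E whose coefficients are non-zero anyway, and
* anomalous edges — pairs inside E whose coefficients are all zero
  (detectable only when lambda_edge > 0).

With equal penalties the problem reduces exactly to the de novo form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lagged import (
    RegularizationPath,
    build_lagged_problem,
    _entries_from_active,
)
from .ordered_lasso import (
    NONZERO_TOL,
    PenaltyWeights,
    fit_time_lagged_ordered_lasso,
    lambda_max,
)


@dataclass(frozen=True)
class PriorNetwork:
    """Known directed edges (source index, target index); may be empty and
    may contain self-pairs."""

    gene_names: tuple
    edges: frozenset

    def __post_init__(self):
        names = tuple(str(g) for g in self.gene_names)
        edges = frozenset((int(j), int(i)) for j, i in self.edges)
        p = len(names)
        for j, i in edges:
            if not (0 <= j < p and 0 <= i < p):
                raise ValueError(f"prior edge ({j}, {i}) is out of range")
        object.__setattr__(self, "gene_names", names)
        object.__setattr__(self, "edges", edges)


@dataclass
class SemiSupervisedResult:
    coefficients: dict  # target index -> CoefficientTensor
    novel_edges: frozenset
    anomalous_edges: frozenset
    lambda_edge: float
    lambda_non_edge: float
    prior: PriorNetwork


def _target_weights(prior, target, n_genes, lambda_edge, lambda_non_edge):
    mult = np.where(
        [(j, target) in prior.edges for j in range(n_genes)],
        lambda_edge,
        lambda_non_edge,
    )
    return PenaltyWeights(mult.astype(float))


def fit_semisupervised(
    data, prior, l_max, lambda_edge, lambda_non_edge, include_self=False
):
    """Fit the two-penalty model for every target and classify edges.

    Per target i the solver receives per-predictor multipliers lambda_edge
    for j with (j, i) in E and lambda_non_edge otherwise (at unit global
    penalty), which with equal values reproduces the de novo fit exactly.
    """
    if lambda_edge < 0 or lambda_non_edge < 0:
        raise ValueError("penalties must be non-negative")
    if lambda_edge > lambda_non_edge:
        warnings.warn(
            "lambda_edge exceeds lambda_non_edge; prior edges are being "
            "penalized more than prior non-edges"
        )
    if tuple(prior.gene_names) != tuple(data.gene_names):
        raise ValueError("prior and dataset name different genes")
    p = data.n_genes
    coefficients = {}
    novel, anomalous = set(), set()
    for i in range(p):
        problem = build_lagged_problem(data, i, l_max)
        weights = _target_weights(prior, i, p, lambda_edge, lambda_non_edge)
        fit = fit_time_lagged_ordered_lasso(problem, 1.0, weights=weights)
        coefficients[i] = fit
        for j in range(p):
            active = np.any(np.abs(fit.w[j, :]) > NONZERO_TOL)
            if (j, i) in prior.edges:
                if not active:
                    anomalous.add((j, i))
            elif active and (include_self or j != i):
                novel.add((j, i))
    return SemiSupervisedResult(
        coefficients=coefficients,
        novel_edges=frozenset(novel),
        anomalous_edges=frozenset(anomalous),
        lambda_edge=float(lambda_edge),
        lambda_non_edge=float(lambda_non_edge),
        prior=prior,
    )


def nonedge_lambda_max(data, prior, l_max, lambda_edge=0.0):
    """Smallest lambda_non_edge at which no prior non-edge is active.

    Per target, the prior-edge groups are fit alone at lambda_edge; the
    critical level for the remaining groups is then the prefix-mean
    criterion applied to the correlation of each non-edge group's
    standardized columns with the residual of that restricted fit.
    Returns the dataset-wide maximum.
    """
    p = data.n_genes
    crit = 0.0
    for i in range(p):
        problem = build_lagged_problem(data, i, l_max)
        prior_js = [j for j in range(p) if (j, i) in prior.edges]
        X, y = problem.design, problem.response
        if prior_js:
            cols = np.concatenate(
                [np.arange(j * l_max, (j + 1) * l_max) for j in prior_js]
            )
            sub = type(problem)(
                design=X[:, cols],
                response=y,
                n_predictors=len(prior_js),
                l_max=l_max,
            )
            sub_fit = fit_time_lagged_ordered_lasso(sub, lambda_edge)
            resid = y - sub_fit.intercept - X[:, cols] @ sub_fit.w.reshape(-1)
        else:
            resid = y - y.mean()
        resid = resid - resid.mean()
        if not np.any(resid):
            continue
        # prefix-mean criterion on standardized non-edge columns
        for j in range(p):
            if j in prior_js:
                continue
            block = X[:, j * l_max : (j + 1) * l_max]
            blockc = block - block.mean(axis=0)
            sd = np.sqrt(np.mean(blockc**2))
            if sd == 0:
                continue
            c = (blockc / sd).T @ resid
            prefix = np.cumsum(c) / np.arange(1, l_max + 1)
            crit = max(crit, float(np.max(np.abs(prefix))))
    return crit


def novel_edge_path(data, prior, l_max, lambda_edge, lambda_grid,
                    include_self=False):
    """Entry values of prior non-edges as lambda_non_edge decreases.

    The grid must be strictly decreasing and should start at or above the
    level at which no prior non-edge is active (see
    :func:`nonedge_lambda_max`); entries obey the same merging rule as the
    de novo path, so thresholded novel-edge sets are nested.
    """
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size < 2 or np.any(grid <= 0) or np.any(np.diff(grid) >= 0):
        raise ValueError("lambda grid must be strictly decreasing, positive")
    if tuple(prior.gene_names) != tuple(data.gene_names):
        raise ValueError("prior and dataset name different genes")
    p = data.n_genes
    entry = {}
    for i in range(p):
        problem = build_lagged_problem(data, i, l_max)
        paths = np.empty((len(grid), p, l_max))
        w_start = None
        for g, lam_ne in enumerate(grid):
            weights = _target_weights(prior, i, p, lambda_edge, lam_ne)
            fit = fit_time_lagged_ordered_lasso(
                problem, 1.0, weights=weights, w_std_init=w_start
            )
            paths[g] = fit.w
            w_start = fit.w_std
        for j in range(p):
            if (j, i) in prior.edges:
                continue
            if j == i and not include_self:
                continue
            active = np.abs(paths[:, j, 0]) > NONZERO_TOL
            entry[(j, i)] = _entries_from_active(active, grid)
    return RegularizationPath(data.gene_names, grid, entry)
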