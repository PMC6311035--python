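"""Reference network-inference methods: pairwise Granger causality and
Lasso-Granger (the same penalized autoregression without the lag-decay
constraint)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from .lagged import (
    DirectedNetwork,
    InvalidConfigurationError,
    build_lagged_problem,
    default_lambda_grid,
    edge_entry_path,
)
from .ordered_lasso import NONZERO_TOL, fit_time_lagged_ordered_lasso


@dataclass(frozen=True)
class GrangerResult:
    """Per-ordered-pair F statistics with BH-adjusted p-values."""

    table: pd.DataFrame  # columns: source, target, F, pvalue, qvalue
    l_max: int
    alpha: float

    def network(self, gene_names, use_fdr=True):
        """Edges whose (adjusted) p-value falls below the threshold."""
        col = "qvalue" if use_fdr else "pvalue"
        edges = {
            (int(r.source), int(r.target))
            for r in self.table.itertuples()
            if getattr(r, col) <= self.alpha
        }
        return DirectedNetwork(gene_names, frozenset(edges))


def _lag_block(series, gene, l_max):
    """Rows t = l_max..T-1 of [x_gene(t-1), ..., x_gene(t-l_max)]."""
    T = series.shape[1]
    return np.column_stack(
        [series[gene, l_max - k : T - k] for k in range(1, l_max + 1)]
    )


def pairwise_granger(data, l_max, alpha=0.05):
    """Pairwise Granger causality over every ordered cross-gene pair.

    For a candidate driver x and target y, the restricted model regresses
    y(t) on an intercept and y's own l_max lags; the full model adds x's
    l_max lags.  Rows are pooled across replicate series (lag windows never
    cross series boundaries) and the explanatory gain is assessed with

        F = ((RSS_r - RSS_f) / l_max) / (RSS_f / df_f),

    df_f = n_rows - (2*l_max + 1).  p-values are BH-adjusted across all
    pairs.  Short series for which df_f <= 0 raise an error — the method's
    inherent limitation for short time courses.
    """
    p = data.n_genes
    n_rows = sum(s.shape[1] - l_max for s in data.series)
    for s_idx, s in enumerate(data.series):
        if s.shape[1] < l_max + 1:
            raise InvalidConfigurationError(
                f"series {s_idx} too short for l_max={l_max}"
            )
    df_full = n_rows - (2 * l_max + 1)
    if df_full <= 0:
        raise InvalidConfigurationError(
            f"pairwise Granger needs positive residual degrees of freedom: "
            f"{n_rows} pooled rows support at most l_max="
            f"{(n_rows - 2) // 2}"
        )

    own = {}
    resp = {}
    for i in range(p):
        own[i] = np.vstack([_lag_block(s, i, l_max) for s in data.series])
        resp[i] = np.concatenate(
            [s[i, l_max:] for s in data.series]
        )
    ones = np.ones((n_rows, 1))

    def rss(X, y):
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    records = []
    for i in range(p):
        y = resp[i]
        rss_r = rss(np.hstack([ones, own[i]]), y)
        for j in range(p):
            if j == i:
                continue
            rss_f = rss(np.hstack([ones, own[i], own[j]]), y)
            if rss_f <= max(1e-12 * max(rss_r, 1.0), 0.0):
                F, pval = np.inf, 0.0
            else:
                F = ((rss_r - rss_f) / l_max) / (rss_f / df_full)
                F = max(F, 0.0)  # numerical guard; nested models
                pval = float(f_dist.sf(F, l_max, df_full))
            records.append((j, i, F, pval))
    table = pd.DataFrame(records, columns=["source", "target", "F", "pvalue"])
    table["qvalue"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    return GrangerResult(table=table, l_max=l_max, alpha=alpha)


def lasso_granger(data, l_max, lam, include_self=False):
    """Lasso-Granger network at one penalty level: the penalized lagged
    autoregression without the monotonicity constraint.  An edge j -> i is
    predicted iff any lag coefficient of j is non-zero (without the
    constraint, all lags must be checked)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    edges = set()
    for i in range(data.n_genes):
        problem = build_lagged_problem(data, i, l_max)
        fit = fit_time_lagged_ordered_lasso(problem, lam, monotone=False)
        for j in range(data.n_genes):
            if j == i and not include_self:
                continue
            if np.any(np.abs(fit.w[j, :]) > NONZERO_TOL):
                edges.add((j, i))
    return DirectedNetwork(data.gene_names, frozenset(edges))


def lasso_granger_path(data, l_max, lambda_grid=None, include_self=False):
    """Edge-entry path for Lasso-Granger (mirrors the de novo path)."""
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(data, l_max, monotone=False)
    return edge_entry_path(
        data, l_max, lambda_grid=lambda_grid, include_self=include_self,
        monotone=False,
    )
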