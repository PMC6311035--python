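"""Validation data generators: repressilator ODE and sparse linear VAR.

The repressilator is the classic three-gene cycle in which each gene
represses the next (z -| x -| y -| z).  With production strength ``alpha``
and Hill coefficient ``n`` its deterministic dynamics are

    dx/dt = alpha / (1 + z^n) - x
    dy/dt = alpha / (1 + x^n) - y
    dz/dt = alpha / (1 + y^n) - z,

which for alpha = 4, n = 3 produce oscillatory expression (a slowly damped
spiral at these parameters, oscillating throughout horizons of a few
periods) from a generic asymmetric initial state.  Sampling the trajectory
at interval ``dt`` over a horizon ``T`` yields a noiseless expression time
course with a known three-edge ground-truth network.

The VAR generator produces sparse linear vector autoregressions with known
support — the exact model class of the lag-monotone autoregression — used for
support-recovery and calibration experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .lagged import (
    DirectedNetwork,
    ExpressionDataset,
    InvalidConfigurationError,
    default_lambda_grid,
    edge_entry_path,
)


@dataclass(frozen=True)
class RepressilatorParams:
    """Repressilator simulation settings.

    ``alpha`` is the maximal production rate (expression units per time),
    ``n`` the Hill coefficient of repression (dimensionless), both > 0.
    The default initial state is asymmetric so the trajectory leaves the
    symmetric invariant manifold and oscillates.
    """

    alpha: float = 4.0
    n: float = 3.0
    initial_state: tuple = (1.0, 1.2, 1.5)
    T: float = 6.0 * np.pi
    dt: float = 6.0 * np.pi / 256.0

    def __post_init__(self):
        if not (self.alpha > 0 and self.n > 0 and self.T > 0 and self.dt > 0):
            raise ValueError("alpha, n, T and dt must all be positive")
        if self.dt > self.T:
            raise ValueError("dt must not exceed the horizon T")
        state = tuple(float(v) for v in self.initial_state)
        if len(state) != 3 or any(v < 0 for v in state):
            raise ValueError("initial_state must be 3 non-negative values")
        object.__setattr__(self, "initial_state", state)


REPRESSILATOR_GENES = ("x", "y", "z")
# each gene is repressed by the previous one in the cycle: z->x, x->y, y->z
REPRESSILATOR_TRUTH = frozenset({(2, 0), (0, 1), (1, 2)})


def repressilator_truth():
    return DirectedNetwork(REPRESSILATOR_GENES, REPRESSILATOR_TRUTH)


def simulate_repressilator(params=None, rtol=1e-8, atol=1e-10):
    """Integrate the repressilator and sample it on a uniform grid.

    Returns
    -------
    (ExpressionDataset, DirectedNetwork)
        The sampled 3-gene single-series dataset and the ground-truth
        network {z->x, x->y, y->z}.
    """
    if params is None:
        params = RepressilatorParams()
    a, n = params.alpha, params.n

    def rhs(_, s):
        x, y, z = s
        return [
            a / (1.0 + z**n) - x,
            a / (1.0 + x**n) - y,
            a / (1.0 + y**n) - z,
        ]

    n_steps = int(np.floor(params.T / params.dt + 1e-9))
    t_eval = np.arange(n_steps + 1) * params.dt
    sol = solve_ivp(
        rhs,
        (0.0, t_eval[-1]),
        np.asarray(params.initial_state, dtype=float),
        method="DOP853",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    data = ExpressionDataset(
        gene_names=REPRESSILATOR_GENES, series=(sol.y,), dt=params.dt
    )
    return data, repressilator_truth()


@dataclass(frozen=True)
class VarModel:
    """Sparse linear vector autoregression with known support.

    ``coefficients[j, i, k]`` propagates gene j at lag k+1 into gene i:

        x_i(t) = sum_j sum_k coefficients[j, i, k] * x_j(t - k - 1) + noise.

    Stationarity (companion-matrix spectral radius < 1) is required.
    """

    coefficients: np.ndarray
    noise_sd: float = 0.0
    monotone_truth: bool = False

    def __post_init__(self):
        A = np.asarray(self.coefficients, dtype=float)
        if A.ndim == 2:
            A = A[:, :, None]
        if A.ndim != 3 or A.shape[0] != A.shape[1]:
            raise ValueError("coefficients must have shape (p, p, l_max_true)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        rho = _companion_spectral_radius(A)
        if rho >= 1.0:
            raise InvalidConfigurationError(
                f"VAR model is non-stationary (spectral radius {rho:.3f})"
            )
        if self.monotone_truth:
            mags = np.abs(A)
            if np.any(np.diff(mags, axis=2) > 1e-12):
                raise ValueError(
                    "monotone_truth requires |A[j,i,k]| non-increasing in k"
                )
        object.__setattr__(self, "coefficients", A)

    @property
    def n_genes(self):
        return self.coefficients.shape[0]

    @property
    def l_max_true(self):
        return self.coefficients.shape[2]

    def truth_network(self, gene_names=None, include_self=False):
        """Edges (j, i) with any non-zero propagation coefficient."""
        p = self.n_genes
        if gene_names is None:
            gene_names = tuple(f"g{j}" for j in range(p))
        edges = {
            (j, i)
            for j in range(p)
            for i in range(p)
            if (include_self or j != i)
            and np.any(self.coefficients[j, i, :] != 0)
        }
        return DirectedNetwork(gene_names, frozenset(edges))


def _companion_spectral_radius(A):
    p, _, l = A.shape
    comp = np.zeros((p * l, p * l))
    for k in range(l):
        comp[:p, k * p : (k + 1) * p] = A[:, :, k].T  # (i, j) propagation
    if l > 1:
        comp[p:, :-p] = np.eye(p * (l - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def random_sparse_var(
    n_genes,
    cross_edges_per_gene=2,
    l_max_true=1,
    self_coef=0.4,
    cross_scale=0.4,
    noise_sd=0.1,
    spectral_radius=0.9,
    seed=0,
):
    """Draw a random sparse stationary VAR with lag-decaying coefficients.

    Every gene gets a self-decay term plus ``cross_edges_per_gene`` incoming
    cross-gene edges with signs drawn at random; magnitudes halve with each
    extra lag so the generating model matches the lag-decay assumption.  The
    whole tensor is rescaled so the companion matrix has the requested
    spectral radius (rescaling preserves the support).
    """
    rng = np.random.default_rng(seed)
    p = n_genes
    A = np.zeros((p, p, l_max_true))
    decay = 0.5 ** np.arange(l_max_true)
    for i in range(p):
        A[i, i, :] = self_coef * decay
        others = [j for j in range(p) if j != i]
        sources = rng.choice(others, size=cross_edges_per_gene, replace=False)
        for j in sources:
            mag = cross_scale * (0.75 + 0.5 * rng.random())
            A[j, i, :] = rng.choice([-1.0, 1.0]) * mag * decay
    rho = _companion_spectral_radius(A)
    if rho > 0:
        A *= spectral_radius / rho
    return VarModel(A, noise_sd=noise_sd, monotone_truth=True)


def ring_var(
    n_genes=6,
    self_coef=0.5,
    cross_coef=0.4,
    l_max_true=1,
    noise_sd=0.0,
    alternate_signs=True,
):
    """Cyclic regulatory cascade: gene j drives gene j+1 (mod p), plus
    self-decay.  The sparse, weakly collinear design keeps the support
    identifiable (the lasso's irrepresentable condition holds comfortably),
    which makes it the fixture of choice for exact-recovery experiments;
    magnitudes halve per extra lag so the truth obeys the lag-decay
    assumption."""
    p = n_genes
    decay = 0.5 ** np.arange(l_max_true)
    A = np.zeros((p, p, l_max_true))
    for j in range(p):
        A[j, j, :] = self_coef * decay
        sign = -1.0 if (alternate_signs and j % 2) else 1.0
        A[j, (j + 1) % p, :] = sign * cross_coef * decay
    return VarModel(A, noise_sd=noise_sd, monotone_truth=True)


def simulate_var(model, T, n_series=1, seed=0, burn_in=200):
    """Simulate ``n_series`` trajectories of length ``T`` from a VAR model.

    With process noise, each series starts from noise and discards a burn-in
    so samples come from the stationary regime.  Without noise the process
    would decay to zero through a burn-in, so instead each series starts
    directly from a random initial state (deterministic transient data).

    Returns (ExpressionDataset, DirectedNetwork) with the generating support
    (cross-gene edges) as the ground truth.
    """
    p, l = model.n_genes, model.l_max_true
    if T < l + 1:
        raise InvalidConfigurationError("T must exceed the true model order")
    rng = np.random.default_rng(seed)
    B = [model.coefficients[:, :, k].T for k in range(l)]  # (i, j) maps
    series = []
    warm = burn_in if model.noise_sd > 0 else 0
    for _ in range(n_series):
        total = warm + T
        x = np.zeros((total, p))
        x[:l] = rng.normal(size=(l, p))
        for t in range(l, total):
            mean = np.zeros(p)
            for k in range(l):
                mean += B[k] @ x[t - k - 1]
            noise = (
                rng.normal(scale=model.noise_sd, size=p)
                if model.noise_sd > 0
                else 0.0
            )
            x[t] = mean + noise
        series.append(x[warm:].T)
    gene_names = tuple(f"g{j}" for j in range(p))
    data = ExpressionDataset(gene_names=gene_names, series=tuple(series), dt=1.0)
    return data, model.truth_network(gene_names)


def experiment_grid(
    T_values,
    dt_values,
    l_max_values,
    methods=("ordered-lasso", "lasso-granger", "granger"),
    params=None,
    n_lambdas=100,
):
    """AUC of each method on repressilator data over a (T, dt, l_max) grid.

    For each cell the repressilator is simulated noiselessly, each method
    ranks the 6 off-diagonal ordered pairs, and the ROC AUC against the 3
    true edges is computed (entry-value ranking for the penalized methods,
    1 - p ranking for pairwise Granger).  Cells whose sampled series is too
    short for the requested l_max are reported as skipped.

    Returns a long-format DataFrame with columns T, dt, l_max, method, auc,
    status.
    """
    from .baselines import lasso_granger_path, pairwise_granger
    from .evaluate import auc_from_entries, auc_from_scores

    if not (len(T_values) and len(dt_values) and len(l_max_values)):
        raise InvalidConfigurationError("parameter grids must be non-empty")
    base = params or RepressilatorParams()
    records = []
    for T in T_values:
        for dt in dt_values:
            if dt > T:
                for l_max in l_max_values:
                    for method in methods:
                        records.append((T, dt, l_max, method, np.nan, "skipped"))
                continue
            cell = RepressilatorParams(
                alpha=base.alpha, n=base.n,
                initial_state=base.initial_state, T=T, dt=dt,
            )
            data, truth = simulate_repressilator(cell)
            T_points = data.series[0].shape[1]
            for l_max in l_max_values:
                for method in methods:
                    needed = (
                        2 * l_max + 2 if method == "granger" else l_max + 1
                    )
                    if T_points < needed:
                        records.append((T, dt, l_max, method, np.nan, "skipped"))
                        continue
                    try:
                        if method == "granger":
                            res = pairwise_granger(data, l_max)
                            scores = {
                                (int(r.source), int(r.target)): 1.0 - r.pvalue
                                for r in res.table.itertuples()
                            }
                            roc = auc_from_scores(
                                scores, truth.edges, data.n_genes
                            )
                        else:
                            monotone = method == "ordered-lasso"
                            grid = default_lambda_grid(
                                data, l_max, n_lambdas=n_lambdas,
                                monotone=monotone,
                            )
                            if monotone:
                                path = edge_entry_path(
                                    data, l_max, lambda_grid=grid
                                )
                            else:
                                path = lasso_granger_path(
                                    data, l_max, lambda_grid=grid
                                )
                            roc = auc_from_entries(path, truth)
                        records.append((T, dt, l_max, method, roc.auc, "ok"))
                    except InvalidConfigurationError:
                        records.append((T, dt, l_max, method, np.nan, "skipped"))
    return pd.DataFrame(
        records, columns=["T", "dt", "l_max", "method", "auc", "status"]
    )
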