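"""Core solver: isotonic projection, penalized fits, critical penalty."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagnet.ordered_lasso import (
    ConvergenceError,
    LaggedProblem,
    PenaltyWeights,
    fit_time_lagged_ordered_lasso,
    lambda_max,
    monotone_nonincreasing_projection,
    _standardize,
)


def brute_force_projection(v, grid_lo=-2.0, grid_hi=8.0, n=81):
    """Exhaustive search of non-increasing sequences on a coarse-to-fine grid."""
    from itertools import product

    best, best_d = None, np.inf
    grid = np.linspace(grid_lo, grid_hi, n)
    for u in product(grid, repeat=len(v)):
        if all(u[i] >= u[i + 1] for i in range(len(u) - 1)):
            d = sum((a - b) ** 2 for a, b in zip(u, v))
            if d < best_d:
                best, best_d = u, d
    return np.asarray(best)


class TestProjection:
    @pytest.mark.parametrize(
        "v, expected",
        [
            ([3, 1], [3, 1]),  # already ordered: identity
            ([1, 3], [2, 2]),  # two adjacent violators pool to their mean
            ([1, 5, 3], [3, 3, 3]),
            ([5.0], [5.0]),
        ],
    )
    def test_known_projections(self, v, expected):
        np.testing.assert_allclose(
            monotone_nonincreasing_projection(v), expected
        )

    def test_matches_exhaustive_search(self):
        v = np.array([1.0, 5.0, 3.0])
        np.testing.assert_allclose(
            monotone_nonincreasing_projection(v),
            brute_force_projection(v),
            atol=0.1,  # limited by the search grid spacing
        )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=1, max_size=8
        )
    )
    def test_projection_properties(self, v):
        """Output is non-increasing, idempotent, mean-preserving, and matches
        scikit-learn's isotonic regression (independent implementation)."""
        u = monotone_nonincreasing_projection(v)
        assert np.all(np.diff(u) <= 1e-9)
        np.testing.assert_allclose(
            monotone_nonincreasing_projection(u), u, atol=1e-12
        )
        assert np.isclose(u.mean(), np.mean(v))
        sklearn_iso = pytest.importorskip("sklearn.isotonic")
        np.testing.assert_allclose(
            u,
            sklearn_iso.isotonic_regression(np.asarray(v), increasing=False),
            atol=1e-9,
        )

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            monotone_nonincreasing_projection([1.0, np.nan])
        with pytest.raises(ValueError):
            monotone_nonincreasing_projection([])


def _problem(X, y, p, l):
    return LaggedProblem(design=X, response=y, n_predictors=p, l_max=l)


class TestFit:
    def test_full_shrinkage_above_lambda_max(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        prob = _problem(X, y, 3, 2)
        lam = lambda_max(prob)
        fit = fit_time_lagged_ordered_lasso(prob, lam * 1.01)
        assert np.all(fit.w == 0)

    def test_univariate_soft_threshold(self):
        """One predictor, one lag, unit-norm column: the solution is the
        soft-thresholded inner product sign(c) * max(|c| - lam, 0)."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        x = (x - x.mean())
        x /= np.sqrt(np.mean(x**2))  # unit SD = unit norm in solver scale
        y = 2.0 * x + 0.1 * rng.normal(size=30)
        prob = _problem(x[:, None], y, 1, 1)
        Xc, yc, *_ = _standardize(prob)
        c = float(Xc[:, 0] @ yc)
        # the unit-norm inner product is not unit in the 0.5*||.||^2 scaling:
        # with sum x^2 = n, the minimizer is (soft(c, lam)) / n
        n = len(y)
        for lam in (0.5, 5.0, abs(c) * 1.1):
            fit = fit_time_lagged_ordered_lasso(prob, lam)
            expected = np.sign(c) * max(abs(c) - lam, 0.0) / n
            assert fit.w_std[0, 0] == pytest.approx(expected, abs=1e-4)

    def test_matches_unconstrained_lasso_at_single_lag(self):
        """With l_max=1 the order constraint is vacuous: the solution must
        match an independent lasso solver coefficient-by-coefficient."""
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(2)
        n, p = 40, 5
        X = rng.normal(size=(n, p))
        y = X @ np.array([1.5, -0.8, 0.0, 0.0, 0.4]) + 0.2 * rng.normal(size=n)
        prob = _problem(X, y, p, 1)
        Xc, yc, *_ = _standardize(prob)
        for lam in (0.2, 1.0, 4.0):
            ours = fit_time_lagged_ordered_lasso(prob, lam)
            ref = sklearn_lm.Lasso(alpha=lam / n, fit_intercept=False)
            ref.fit(Xc, yc)
            np.testing.assert_allclose(
                ours.w_std.reshape(-1), ref.coef_, atol=1e-4
            )

    def test_objective_history_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        fit = fit_time_lagged_ordered_lasso(_problem(X, y, 3, 2), 0.3)
        assert np.all(np.diff(fit.objective_history) <= 0)

    def test_monotone_magnitudes_on_fits(self):
        """Fits to data generated by the assumed model class (lag-decaying,
        sign-consistent influence) satisfy the |w| ordering.  Note the
        positive/negative-part formulation guarantees the ordering within
        each sign; pure-noise responses can produce sign-alternating lag
        profiles where the plain |w| chain breaks across the sign change."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            X = rng.normal(size=(30, 8))
            w_true = np.zeros((2, 4))
            for j in range(2):
                mags = np.sort(rng.uniform(0.2, 1.0, size=4))[::-1]
                w_true[j] = rng.choice([-1.0, 1.0]) * mags
            y = X @ w_true.reshape(-1) + 0.2 * rng.normal(size=30)
            fit = fit_time_lagged_ordered_lasso(
                _problem(X, y, 2, 4), float(rng.uniform(0.05, 2.0))
            )
            assert fit.monotonicity_violation() <= 1e-9

    def test_zero_variance_response_gives_zero_fit(self):
        X = np.random.default_rng(5).normal(size=(12, 4))
        y = np.full(12, 3.7)
        fit = fit_time_lagged_ordered_lasso(_problem(X, y, 2, 2), 0.5)
        assert np.all(fit.w == 0)
        assert fit.intercept == pytest.approx(3.7)

    def test_objective_not_worse_than_zero_vector(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        prob = _problem(X, y, 2, 2)
        _, yc, *_ = _standardize(prob)
        fit = fit_time_lagged_ordered_lasso(prob, 0.1)
        assert fit.objective <= 0.5 * float(yc @ yc) + 1e-12

    def test_convergence_error_carries_diagnostics(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        with pytest.raises(ConvergenceError) as err:
            fit_time_lagged_ordered_lasso(
                _problem(X, y, 2, 2), 0.01, max_iter=3
            )
        assert err.value.last_coefficients is not None
        assert len(err.value.objective_history) >= 1


class TestLambdaMax:
    def test_orthogonal_response_gives_zero(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to both columns
        prob = _problem(X, y, 2, 1)
        assert lambda_max(prob) == pytest.approx(0.0, abs=1e-12)

    def test_single_column_threshold(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=25)
        y = 1.3 * x + 0.2 * rng.normal(size=25)
        prob = _problem(x[:, None], y, 1, 1)
        Xc, yc, *_ = _standardize(prob)
        assert lambda_max(prob) == pytest.approx(abs(Xc[:, 0] @ yc))

    @pytest.mark.parametrize("monotone", [True, False])
    def test_verified_by_direct_fitting(self, monotone):
        """Just above the critical value the fit is identically zero; just
        below it at least one coefficient is active."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 6))
        y = X @ np.array([0.8, 0.4, -0.5, -0.25, 0.0, 0.0]) + 0.1 * rng.normal(
            size=30
        )
        prob = _problem(X, y, 3, 2)
        L = lambda_max(prob, monotone=monotone)
        hi = fit_time_lagged_ordered_lasso(prob, 1.01 * L, monotone=monotone)
        lo = fit_time_lagged_ordered_lasso(prob, 0.9 * L, monotone=monotone)
        assert np.all(hi.w == 0)
        assert np.any(np.abs(lo.w) > 1e-10)

    def test_penalty_weights_rescale_threshold(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        prob = _problem(X, y, 2, 1)
        base = lambda_max(prob)
        halved = lambda_max(prob, weights=PenaltyWeights(np.array([2.0, 2.0])))
        assert halved == pytest.approx(base / 2.0)

    def test_zero_variance_response_warns(self):
        X = np.random.default_rng(11).normal(size=(10, 2))
        with pytest.warns(UserWarning):
            assert lambda_max(_problem(X, np.ones(10), 2, 1)) == 0.0
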