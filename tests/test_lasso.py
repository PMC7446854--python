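"""L1-penalized multinomial logistic regression against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from mbpredict.lasso import (
    _one_hot,
    cv_select_lambda,
    fit_lasso_mlr,
    fit_lasso_path,
    fit_mlr_ridge,
    kkt_violations,
    lambda_grid,
    objective,
    predict_proba,
    stratified_folds,
)


def split_variable_oracle(X, y, lam, penalized, K):
    """Independent convex solver for the penalized objective.

    The L1 term is linearized by β = β⁺ − β⁻ with box constraints
    β± ≥ 0, making the problem smooth and solvable by L-BFGS-B.
    """
    classes = np.unique(y)
    Y = _one_hot(y, classes)
    n, p = X.shape

    def fun(flat):
        Bp = flat[: K * p].reshape(K, p)
        Bm = flat[K * p :].reshape(K, p)
        B = Bp - Bm
        logits = X @ B.T
        zc = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(zc)
        P = e / e.sum(axis=1, keepdims=True)
        nll = float(np.sum(np.log(e.sum(axis=1)) - (zc * Y).sum(axis=1)))
        pen = lam * (Bp[:, penalized].sum() + Bm[:, penalized].sum())
        g = (P - Y).T @ X
        gp = g + lam * penalized[None, :]
        gm = -g + lam * penalized[None, :]
        return nll + pen, np.concatenate([gp.ravel(), gm.ravel()])

    x0 = np.zeros(2 * K * p)
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * K * p),
                   options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-10})
    return res.fun


def _toy_problem(seed=0, n=20, p=3, K=2):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    beta = np.concatenate([[0.2], rng.normal(size=p)])
    y = (X @ beta + rng.normal(size=n) > 0).astype(int)
    if len(np.unique(y)) < K:
        y[0] = 1 - y[0]
    penalized = np.ones(p + 1, dtype=bool)
    penalized[0] = False
    return X, y, penalized


class TestSolver:
    def test_lambda_max_zeroes_everything_and_predicts_frequencies(self):
        X, y, pen = _toy_problem(1)
        grid = lambda_grid(X, y, n_lambda=5, penalized=pen)
        B, conv = fit_lasso_mlr(X, y, grid[0], penalized=pen)
        assert conv
        assert np.allclose(B[:, pen], 0.0)
        proba = predict_proba(B, X)
        freq = np.bincount(y) / y.size
        assert np.allclose(proba, freq[None, :], atol=1e-4)

    def test_just_below_lambda_max_activates_a_coefficient(self):
        X, y, pen = _toy_problem(1)
        grid = lambda_grid(X, y, n_lambda=5, penalized=pen)
        B, _ = fit_lasso_mlr(X, y, grid[0] * 0.95, penalized=pen)
        assert np.abs(B[:, pen]).max() > 0

    @pytest.mark.parametrize("seed,K", [(0, 2), (1, 2), (2, 3)])
    def test_objective_matches_independent_convex_solver(self, seed, K):
        rng = np.random.default_rng(seed)
        n, p = 20, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        y = rng.integers(0, K, n)
        for k in range(K):  # ensure all classes appear
            y[k] = k
        pen = np.ones(p + 1, dtype=bool)
        pen[0] = False
        lam = 2.0
        B, conv = fit_lasso_mlr(X, y, lam, penalized=pen, tol=1e-12, max_iter=20000)
        ours = objective(B, X, _one_hot(y, np.unique(y)), lam, pen)
        oracle = split_variable_oracle(X, y, lam, pen, K)
        assert ours == pytest.approx(oracle, abs=1e-5)

    def test_duplicated_column_keeps_objective(self):
        X, y, pen = _toy_problem(3)
        lam = 1.0
        B1, _ = fit_lasso_mlr(X, y, lam, penalized=pen, tol=1e-12)
        Y = _one_hot(y, np.unique(y))
        obj1 = objective(B1, X, Y, lam, pen)
        Xd = np.column_stack([X, X[:, 1]])
        pend = np.append(pen, True)
        B2, _ = fit_lasso_mlr(Xd, y, lam, penalized=pend, tol=1e-12)
        obj2 = objective(B2, Xd, Y, lam, pend)
        assert obj2 == pytest.approx(obj1, abs=1e-5)

    def test_kkt_holds_at_convergence(self):
        X, y, pen = _toy_problem(4, n=40, p=6)
        lam = 3.0
        B, _ = fit_lasso_mlr(X, y, lam, penalized=pen, tol=1e-12)
        assert kkt_violations(B, X, _one_hot(y, np.unique(y)), lam, pen, tol=1e-4).size == 0

    def test_objective_monotone_in_debug_mode(self):
        X, y, pen = _toy_problem(5, n=30, p=4)
        fit_lasso_mlr(X, y, 0.5, penalized=pen, debug=True)  # asserts internally

    def test_symmetric_k2_fit_matches_binary_difference_parameterization(self):
        # oracle: binary logistic LASSO on the coefficient difference δ = β₁ − β₀,
        # whose minimal symmetric representation carries the same penalty ‖δ‖₁
        X, y, pen = _toy_problem(6, n=50, p=4)
        lam = 1.5
        B, _ = fit_lasso_mlr(X, y, lam, penalized=pen, tol=1e-12)
        ours = predict_proba(B, X)[:, 1]

        def binary_obj(delta):
            eta = X @ delta
            nll = np.sum(np.logaddexp(0, eta) - y * eta)
            return nll + lam * np.abs(delta[pen]).sum()

        # smooth split form for the oracle
        p_ = X.shape[1]

        def fun(flat):
            d = flat[:p_] - flat[p_:]
            eta = X @ d
            pr = 1 / (1 + np.exp(-eta))
            nll = float(np.sum(np.logaddexp(0, eta) - y * eta))
            g = X.T @ (pr - y)
            return (nll + lam * (flat[:p_][pen].sum() + flat[p_:][pen].sum()),
                    np.concatenate([g + lam * pen, -g + lam * pen]))

        res = minimize(fun, np.zeros(2 * p_), jac=True, method="L-BFGS-B",
                       bounds=[(0, None)] * 2 * p_, options={"ftol": 1e-15})
        delta = res.x[:p_] - res.x[p_:]
        oracle = 1 / (1 + np.exp(-(X @ delta)))
        assert np.allclose(ours, oracle, atol=1e-4)


class TestGrid:
    def test_two_point_grid(self):
        X, y, pen = _toy_problem(0)
        g = lambda_grid(X, y, n_lambda=2, ratio=1e-3, penalized=pen)
        assert g.size == 2
        assert g[1] == pytest.approx(g[0] * 1e-3)

    def test_strictly_decreasing(self):
        X, y, pen = _toy_problem(0)
        g = lambda_grid(X, y, n_lambda=50, penalized=pen)
        assert np.all(np.diff(g) < 0)

    def test_single_class_is_an_error(self):
        X, _, pen = _toy_problem(0)
        with pytest.raises(ValueError):
            lambda_grid(X, np.zeros(X.shape[0], dtype=int), penalized=pen)

    def test_path_sparsity_nonincreasing_in_lambda(self):
        X, y, pen = _toy_problem(8, n=60, p=8)
        grid = lambda_grid(X, y, n_lambda=25, ratio=1e-3, penalized=pen)
        path = fit_lasso_path(X, y, grid, penalized=pen)
        nnz = [int((B[:, pen] != 0).any(axis=0).sum()) for B in path.coef_sets]
        # grid is descending, so activity grows (allow 1-column numerical slack)
        assert all(b >= a - 1 for a, b in zip(nnz, nnz[1:]))


class TestCV:
    def test_single_candidate_grid_is_returned(self):
        X, y, _ = _toy_problem(0)
        lam, cv = cv_select_lambda(X, y, np.array([0.7]), k=4, seed=0)
        assert lam == 0.7 and cv.shape == (1,)

    def test_ties_break_to_larger_lambda(self):
        # a grid far above every fold's lambda_max with unbalanced classes:
        # every fit is the null model predicting the majority class, CV
        # errors tie exactly, and the larger lambda must win
        rng = np.random.default_rng(1)
        n = 24
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = np.array([0] * 16 + [1] * 8)
        pen = np.ones(4, dtype=bool)
        pen[0] = False
        lam_max = lambda_grid(X, y, n_lambda=2, penalized=pen)[0]
        lam, cv = cv_select_lambda(X, y, np.array([lam_max * 40, lam_max * 20]),
                                   k=4, seed=0, penalized=pen)
        assert lam == pytest.approx(lam_max * 40)
        assert cv[0] == cv[1]

    def test_stratified_folds_cover_classes(self):
        y = np.array([0] * 30 + [1] * 10)
        folds = stratified_folds(y, 5, np.random.default_rng(0))
        for f in range(5):
            assert set(y[folds == f]) == {0, 1}

    def test_pure_noise_cv_error_near_baseline(self):
        rng = np.random.default_rng(42)
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 10))])
        y = np.array([0] * 72 + [1] * 48)
        pen = np.ones(11, dtype=bool)
        pen[0] = False
        grid = lambda_grid(X, y, n_lambda=30, ratio=1e-2, penalized=pen)
        lam, cv = cv_select_lambda(X, y, grid, k=5, seed=1, penalized=pen)
        assert cv.min() == pytest.approx(0.4, abs=0.08)


class TestRidgeGLM:
    def test_separable_data_stays_finite(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = (np.arange(10) >= 5).astype(int)
        B = fit_mlr_ridge(X, y, ridge=1e-6)
        assert np.all(np.isfinite(B))
        proba = predict_proba(B, X)
        assert np.all(np.isfinite(proba))
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_matches_statsmodels_logit_when_unseparable(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = (X @ np.array([0.3, 1.0, -0.7]) + rng.logistic(size=n) > 0).astype(int)
        B = fit_mlr_ridge(X, y, ridge=1e-10)
        delta = B[1] - B[0]  # symmetric -> difference parameterization
        ref = sm.Logit(y, X).fit(disp=0).params
        assert np.allclose(delta, ref, atol=1e-4)
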