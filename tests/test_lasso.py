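"""Solver correctness: closed forms, KKT, exact enumeration oracle, CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clpnet.lasso import (
    ConvergenceError,
    build_lambda_path,
    cv_select_lambda,
    kkt_violation,
    lasso_fit,
    lasso_objective,
    lasso_path,
    soft_threshold,
)


def exact_lasso_by_enumeration(X, y, lam):
    """Independent oracle: enumerate all 3^p sign patterns.

    For each candidate pattern s, solve the stationarity system on the
    active set, G_SS b_S = c_S - lam*s_S, and keep it if signs agree and
    the zero coordinates satisfy |c - G b| <= lam.  Returns the feasible
    solution with the smallest objective.  Assumes centered/population-
    standardized inputs, matching the solver's internal scale.
    """
    from itertools import product

    n, p = X.shape
    G = X.T @ X / n
    c = X.T @ y / n
    best, best_obj = None, np.inf
    for signs in product((-1, 0, 1), repeat=p):
        s = np.array(signs, dtype=float)
        active = s != 0
        b = np.zeros(p)
        if active.any():
            try:
                b[active] = np.linalg.solve(G[np.ix_(active, active)],
                                            c[active] - lam * s[active])
            except np.linalg.LinAlgError:
                continue
            if np.any(np.sign(b[active]) != s[active]):
                continue
        grad = c - G @ b
        if np.any(np.abs(grad[~active]) > lam + 1e-10):
            continue
        obj = 0.5 * np.mean((y - X @ b) ** 2) + lam * np.abs(b).sum()
        if obj < best_obj:
            best_obj, best = obj, b
    return best, best_obj


def standardized_problem(rng, n, p, sparsity=2, noise=0.5):
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.zeros(p)
    beta[:sparsity] = rng.uniform(0.5, 1.5, sparsity) * rng.choice([-1, 1], sparsity)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y - y.mean()


class TestSoftThreshold:
    @pytest.mark.parametrize("z, t, expected", [
        (2.0, 0.0, 2.0),
        (0.5, 1.0, 0.0),
        (-3.0, 1.0, -2.0),
        (1.0, 1.0, 0.0),
    ])
    def test_examples(self, z, t, expected):
        assert soft_threshold(z, t) == expected

    @settings(deadline=None, max_examples=100)
    @given(st.floats(-100, 100), st.floats(0, 50))
    def test_shrinks_toward_zero_preserving_sign(self, z, t):
        out = soft_threshold(z, t)
        assert abs(out) <= abs(z) + 1e-12
        assert out * z >= 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestLambdaPath:
    def test_first_lambda_gives_empty_support(self):
        rng = np.random.default_rng(0)
        X, y = standardized_problem(rng, 80, 5)
        path = build_lambda_path(X, y)
        coef, _ = lasso_fit(X, y, path.lambdas[0])
        assert np.all(coef == 0)
        # and just below it, something enters
        coef2, _ = lasso_fit(X, y, path.lambdas[0] * 0.99)
        assert np.any(coef2 != 0)

    def test_path_strictly_decreasing_log_spaced(self):
        rng = np.random.default_rng(1)
        X, y = standardized_problem(rng, 50, 4)
        path = build_lambda_path(X, y, n_lambdas=60, ratio_min=1e-2)
        assert len(path.lambdas) == 60
        assert np.all(np.diff(path.lambdas) < 0)
        ratios = path.lambdas[1:] / path.lambdas[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_lambda_max_matches_hand_inner_products(self):
        # two standardized predictors with hand-computable correlations
        X = np.array([[1.0, -1.0], [-1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])
        y = np.array([2.0, -1.0, 1.0, -2.0])
        # <x1,y>/n = (2+1+1+2)/4 = 1.5 ; <x2,y>/n = (-2+1+1-2)/4 = -0.5
        path = build_lambda_path(X, y, n_lambdas=10)
        assert path.lambdas[0] == pytest.approx(1.5)

    def test_constant_response_rejected(self):
        X = np.random.default_rng(2).standard_normal((20, 3))
        with pytest.raises(ValueError):
            build_lambda_path(X, np.ones(20))


class TestLassoFit:
    def test_orthonormal_design_soft_thresholds_ols(self):
        """On an orthonormal design the LASSO solution is soft_threshold
        applied to the per-coordinate OLS estimates."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n, p = 64, 4
            Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
            X = Q * np.sqrt(n)  # X'X/n = I, columns mean-centered below
            X = X - X.mean(0)
            X = X / X.std(0)
            # re-orthonormalize after centering
            Q, _ = np.linalg.qr(X)
            X = Q * np.sqrt(n)
            y = rng.standard_normal(n)
            y = y - y.mean()
            lam = rng.uniform(0.01, 0.3)
            ols = X.T @ y / n
            expected = soft_threshold(ols, lam)
            coef, _ = lasso_fit(X, y, lam)
            # internal scaling is near-identity; compare on the output scale
            np.testing.assert_allclose(coef * X.std(0), expected, atol=1e-6)

    def test_zero_penalty_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        X, y = standardized_problem(rng, 100, 5)
        coef, intercept = lasso_fit(X, y, 0.0)
        Xd = np.column_stack([np.ones(len(y)), X])
        ols = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        np.testing.assert_allclose(intercept, ols[0], atol=1e-6)
        np.testing.assert_allclose(coef, ols[1:], atol=1e-6)

    def test_matches_exact_enumeration_oracle(self):
        """Objective and coefficients agree with exhaustive sign-pattern
        enumeration on random small instances."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(20, 50))
            p = int(rng.integers(2, 6))
            X, y = standardized_problem(rng, n, p, sparsity=min(2, p))
            lam = float(rng.uniform(0.02, 0.5))
            coef, intercept = lasso_fit(X, y, lam)
            oracle_coef, oracle_obj = exact_lasso_by_enumeration(X, y, lam)
            obj = lasso_objective(X, y, coef, intercept, lam)
            assert abs(obj - oracle_obj) < 1e-5
            np.testing.assert_allclose(coef, oracle_coef, atol=1e-5)

    def test_local_optimality_under_perturbation(self):
        rng = np.random.default_rng(6)
        X, y = standardized_problem(rng, 40, 5)
        lam = 0.1
        coef, intercept = lasso_fit(X, y, lam)
        base = lasso_objective(X, y, coef, intercept, lam)
        for _ in range(1000):
            pert = coef + rng.normal(0, 0.01, coef.shape)
            assert lasso_objective(X, y, pert, intercept, lam) >= base - 1e-10

    def test_kkt_conditions_hold(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            X, y = standardized_problem(rng, int(rng.integers(30, 80)),
                                        int(rng.integers(2, 7)))
            lam = float(rng.uniform(0.01, 0.6))
            coef, intercept = lasso_fit(X, y, lam, tol=1e-10)
            assert kkt_violation(X, y, coef, intercept, lam) < 1e-6

    def test_support_monotone_along_path(self):
        rng = np.random.default_rng(8)
        X, y = standardized_problem(rng, 120, 6, sparsity=3, noise=0.3)
        path = build_lambda_path(X, y, n_lambdas=50)
        coefs, _ = lasso_path(X, y, path.lambdas)
        sizes = (coefs != 0).sum(axis=1)
        # support grows (weakly) as the penalty relaxes, up to rare swaps
        assert sizes[0] == 0
        assert np.all(np.diff(sizes) >= 0)

    def test_nonconvergence_carries_last_iterate(self):
        rng = np.random.default_rng(9)
        X, y = standardized_problem(rng, 40, 5)
        with pytest.raises(ConvergenceError) as err:
            lasso_fit(X, y, 0.001, tol=1e-14, max_iter=1)
        assert err.value.coef is not None

    def test_missing_cells_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            lasso_fit(X, np.zeros(10), 0.1)


class TestCrossValidation:
    def test_same_seed_same_selection(self):
        rng = np.random.default_rng(10)
        X, y = standardized_problem(rng, 100, 5)
        path = build_lambda_path(X, y)
        a = cv_select_lambda(X, y, path, k=10, seed=3)
        b = cv_select_lambda(X, y, path, k=10, seed=3)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])

    def test_true_predictor_selected_under_low_noise(self):
        """With one strong true predictor, the CV-selected model contains
        it nearly always (simulation oracle, 50 reps)."""
        rng = np.random.default_rng(11)
        hits = 0
        for r in range(50):
            X = rng.standard_normal((80, 5))
            y = 1.0 * X[:, 2] + 0.05 * rng.standard_normal(80)
            path = build_lambda_path(X, y)
            lam, _, _ = cv_select_lambda(X, y, path, k=10, seed=r)
            coef, _ = lasso_fit(X, y, lam)
            hits += coef[2] != 0
        assert hits >= 48

    def test_pure_noise_median_support_small(self):
        """CV-min on pure noise keeps the model essentially empty."""
        rng = np.random.default_rng(12)
        supports = []
        for r in range(30):
            X = rng.standard_normal((500, 6))
            y = rng.standard_normal(500)
            path = build_lambda_path(X, y)
            lam, _, _ = cv_select_lambda(X, y, path, k=10, seed=r)
            coef, _ = lasso_fit(X, y, lam)
            supports.append(int((coef != 0).sum()))
        assert np.median(supports) <= 1

    def test_one_se_rule_sparser_than_min(self):
        rng = np.random.default_rng(13)
        X, y = standardized_problem(rng, 150, 6, sparsity=3, noise=1.0)
        path = build_lambda_path(X, y)
        lam_min, _, _ = cv_select_lambda(X, y, path, k=10, seed=1, rule="min")
        lam_1se, _, _ = cv_select_lambda(X, y, path, k=10, seed=1, rule="one_se")
        assert lam_1se >= lam_min

    def test_more_folds_than_observations_rejected(self):
        X = np.random.default_rng(14).standard_normal((5, 2))
        y = np.arange(5.0)
        path = build_lambda_path(X, y)
        with pytest.raises(ValueError):
            cv_select_lambda(X, y, path, k=10)
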