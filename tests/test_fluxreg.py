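"""OLS/GLS estimation, covariance propagation and the regression ANOVA."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import sympy
from hypothesis import given, settings, strategies as st
from scipy import stats

from fluxdiag import (RegressionProblem, build_regression, gls_fit, ols_fit,
                      partition, regression_anova, whiten_problem)
from tests.conftest import random_overdetermined


class TestBuildRegression:
    def test_response_is_negative_exchange_flow(self, toy_model, toy_measurements):
        pm = partition(toy_model, toy_measurements)
        problem = build_regression(pm)
        np.testing.assert_allclose(problem.y, -pm.S_E @ pm.v_E)
        np.testing.assert_array_equal(problem.X, pm.S_I)

    def test_cov_matches_hand_product(self):
        # 3 metabolites, 2 exchanges: Cov = S_E diag(sd^2) S_E'
        from fluxdiag import MetabolicModel
        S = np.array([[1.0, 0.0, -1.0],
                      [1.0, -1.0, 1.0],
                      [0.0, 1.0, -1.0]])
        model = MetabolicModel(["A", "B", "C"], ["EX_A", "EX_B", "R1"], S)
        meas = pd.DataFrame({"reaction_id": ["EX_A", "EX_B"],
                             "value": [1.0, 2.0], "sd": [0.3, 0.5]})
        pm = partition(model, meas)
        problem = build_regression(pm)
        hand = np.array([[0.09, 0.09, 0.0],
                         [0.09, 0.09 + 0.25, -0.25],
                         [0.0, -0.25, 0.25]])
        d = np.diag(problem.cov_e) - np.diag(hand)
        # off-diagonals exact; diagonal may carry the variance floor
        np.testing.assert_allclose(problem.cov_e - np.diag(np.diag(problem.cov_e)),
                                   hand - np.diag(np.diag(hand)), atol=1e-15)
        assert (d >= 0).all() and d.max() < 1e-6 * 0.09 * 1.01

    def test_zero_sd_gets_floor(self, toy_model):
        meas = pd.DataFrame({"reaction_id": ["EX_A"], "value": [2.0], "sd": [0.0]})
        pm = partition(toy_model, meas)
        with pytest.warns(UserWarning):
            problem = build_regression(pm)
        assert np.all(np.diag(problem.cov_e) > 0)
        np.linalg.cholesky(problem.cov_e)  # positive definite


class TestOlsFit:
    def test_identity_design(self):
        y = np.array([3.0, -1.0, 2.0])
        est = ols_fit(RegressionProblem(y=y, X=np.eye(3)))
        np.testing.assert_allclose(est.beta_hat, y)
        assert est.sse == pytest.approx(0.0, abs=1e-25)

    def test_noiseless_recovery(self, rng):
        X, beta, y = random_overdetermined(rng, n=15, k=6, noise=0.0)
        est = ols_fit(RegressionProblem(y=y, X=X))
        np.testing.assert_allclose(est.beta_hat, beta, atol=1e-9)

    def test_matches_exact_rational_normal_equations(self):
        rng = np.random.default_rng(7)
        X = rng.integers(-4, 5, size=(6, 3)).astype(float)
        while np.linalg.matrix_rank(X) < 3:
            X = rng.integers(-4, 5, size=(6, 3)).astype(float)
        y = rng.integers(-9, 10, size=6).astype(float)
        Xs = sympy.Matrix(X.astype(int))
        ys = sympy.Matrix(y.astype(int))
        exact = (Xs.T * Xs).solve(Xs.T * ys)
        np.testing.assert_allclose(
            ols_fit(RegressionProblem(y=y, X=X)).beta_hat,
            np.array(exact, dtype=float).ravel(), rtol=1e-12)

    def test_matches_statsmodels(self, rng):
        X, _, y = random_overdetermined(rng, n=20, k=4, noise=0.5)
        est = ols_fit(RegressionProblem(y=y, X=X))
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(est.beta_hat, ref.params, rtol=1e-10)
        np.testing.assert_allclose(est.standard_errors, ref.bse, rtol=1e-10)
        assert est.sse == pytest.approx(ref.ssr, rel=1e-12)

    def test_residuals_orthogonal_to_design(self, rng):
        X, _, y = random_overdetermined(rng, n=18, k=5, noise=1.0)
        est = ols_fit(RegressionProblem(y=y, X=X))
        assert np.max(np.abs(X.T @ est.residuals)) < 1e-10


class TestGlsFit:
    def test_scalar_covariance_reduces_to_ols(self, rng):
        X, _, y = random_overdetermined(rng, n=12, k=4, noise=1.0)
        for c in (0.5, 3.0):
            gls = gls_fit(RegressionProblem(y=y, X=X, cov_e=c * np.eye(12)))
            ols = ols_fit(RegressionProblem(y=y, X=X))
            np.testing.assert_allclose(gls.beta_hat, ols.beta_hat, rtol=1e-12)

    def test_huge_variance_downweights_row(self, rng):
        X, _, y = random_overdetermined(rng, n=10, k=3, noise=1.0)
        devs = []
        for big in (1e4, 1e8):
            var = np.ones(10)
            var[0] = big
            gls = gls_fit(RegressionProblem(y=y, X=X, cov_e=np.diag(var)))
            drop = ols_fit(RegressionProblem(y=y[1:], X=X[1:]))
            devs.append(np.linalg.norm(gls.beta_hat - drop.beta_hat))
        assert devs[1] < devs[0]  # monotone approach to the row-dropped fit
        assert devs[1] < 1e-6

    def test_matches_direct_formula(self, rng):
        # independent evaluation with explicit matrix inversion
        X, _, y = random_overdetermined(rng, n=6, k=3, noise=1.0)
        var = np.linspace(0.5, 3.0, 6)
        cov = np.diag(var)
        W = np.linalg.inv(cov)
        direct = np.linalg.inv(X.T @ W @ X) @ X.T @ W @ y
        est = gls_fit(RegressionProblem(y=y, X=X, cov_e=cov))
        np.testing.assert_allclose(est.beta_hat, direct, rtol=1e-10)
        np.testing.assert_allclose(est.cov_beta, np.linalg.inv(X.T @ W @ X),
                                   rtol=1e-10)

    def test_whitening_equivalence(self, rng):
        X, _, y = random_overdetermined(rng, n=14, k=5, noise=1.0)
        A = rng.normal(size=(14, 14))
        cov = A @ A.T + 14 * np.eye(14)
        problem = RegressionProblem(y=y, X=X, cov_e=cov)
        gls = gls_fit(problem)
        white = ols_fit(whiten_problem(problem))
        np.testing.assert_allclose(gls.beta_hat, white.beta_hat, rtol=1e-10)
        assert gls.sse == pytest.approx(white.sse, rel=1e-10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(0, 10_000))
    def test_gauss_markov_reduction_property(self, c, seed):
        rng = np.random.default_rng(seed)
        X, _, y = random_overdetermined(rng, n=9, k=3, noise=1.0)
        gls = gls_fit(RegressionProblem(y=y, X=X, cov_e=c * np.eye(9)))
        ols = ols_fit(RegressionProblem(y=y, X=X))
        np.testing.assert_allclose(gls.beta_hat, ols.beta_hat,
                                   rtol=1e-9, atol=1e-12)


class TestRegressionAnova:
    def test_overwhelming_signal(self, rng):
        X, _, _ = random_overdetermined(rng, n=20, k=3)
        beta = np.array([10.0, -8.0, 12.0])
        y = X @ beta + 1e-4 * rng.normal(size=20)
        problem = RegressionProblem(y=y, X=X)
        anova = regression_anova(ols_fit(problem), problem)
        assert anova.p_value < 1e-6

    def test_exact_fit_flagged(self):
        X = np.eye(3)[:, :1]
        y = np.array([2.0, 0.0, 0.0])
        problem = RegressionProblem(y=y, X=X)
        anova = regression_anova(ols_fit(problem), problem)
        assert anova.exact_fit and anova.p_value == 0.0

    def test_k1_n3_hand_example(self):
        # y = (1, 2, 2), x = (1, 1, 2): bhat = 7/6, SSE = y'y - bhat^2 * x'x
        x = np.array([[1.0], [1.0], [2.0]])
        y = np.array([1.0, 2.0, 2.0])
        problem = RegressionProblem(y=y, X=x)
        anova = regression_anova(ols_fit(problem), problem)
        bhat = 7.0 / 6.0
        ssr = bhat ** 2 * 6.0
        sse = 9.0 - ssr
        f_hand = (ssr / 1) / (sse / 2)
        assert anova.f_statistic == pytest.approx(f_hand, rel=1e-12)
        assert anova.p_value == pytest.approx(stats.f.sf(f_hand, 1, 2), rel=1e-12)

    def test_null_calibration(self):
        # pure-noise y: p uniform, rejection rate ~ alpha
        rng = np.random.default_rng(42)
        X = rng.normal(size=(10, 2))
        reject = 0
        reps = 2000
        for _ in range(reps):
            y = rng.normal(size=10)
            problem = RegressionProblem(y=y, X=X)
            reject += regression_anova(ols_fit(problem), problem).p_value <= 0.05
        assert abs(reject / reps - 0.05) < 0.02
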