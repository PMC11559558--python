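"""Nodewise OLS/lasso estimation and network stitching."""

import numpy as np
import pytest
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from ggminfer import DataMatrix, ModelError, PrecisionModel, sample_gaussian
from ggminfer._lasso import cv_lasso, lambda_max, lasso_fixed
from ggminfer.nodewise import (
    fit_lasso_node,
    fit_network,
    fit_ols_node,
    glasso_ebic,
    ebic_score,
    threshold_lasso,
)


def _chain_model(p=4, w=0.4):
    theta = np.eye(p)
    for k in range(p - 1):
        theta[k, k + 1] = theta[k + 1, k] = -w
    return PrecisionModel(theta)


class TestCvLassoWrapper:
    def test_matches_sklearn_lassocv(self, rng):
        # independent route: sklearn's own CV estimator on the same grid/folds
        X = rng.standard_normal((120, 8))
        y = X[:, 0] * 0.8 - X[:, 3] * 0.5 + rng.standard_normal(120)
        X, y = X - X.mean(0), y - y.mean()
        lam_max = lambda_max(X, y)
        alphas = np.geomspace(lam_max, 1e-4 * lam_max, 100)
        coef, lam = cv_lasso(X, y, seed=7)
        ref = LassoCV(alphas=alphas, fit_intercept=False,
                      cv=KFold(10, shuffle=True, random_state=7)).fit(X, y)
        assert lam == pytest.approx(ref.alpha_)
        assert np.allclose(coef, ref.coef_, atol=1e-6)


class TestOlsNode:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 3))
        X[:, 0] = 2.0 * X[:, 1] - X[:, 2]
        fit = fit_ols_node(DataMatrix(X), 0)
        assert np.max(np.abs(fit.residuals)) < 1e-10

    def test_bivariate_closed_form(self, rng):
        X = rng.standard_normal((50, 2))
        fit = fit_ols_node(DataMatrix(X), 0)
        xc = X - X.mean(0)
        expected = (xc[:, 1] @ xc[:, 0]) / (xc[:, 1] @ xc[:, 1])
        assert fit.coefficients[0] == pytest.approx(expected)

    def test_matches_normal_equations(self, rng):
        X = rng.standard_normal((20, 5))
        fit = fit_ols_node(DataMatrix(X), 2)
        Xc = X - X.mean(0)
        D = Xc[:, [0, 1, 3, 4]]
        beta = np.linalg.solve(D.T @ D, D.T @ Xc[:, 2])
        assert np.allclose(fit.coefficients, beta, atol=1e-10)
        assert fit.sigma2_hat == pytest.approx(
            float((Xc[:, 2] - D @ beta) @ (Xc[:, 2] - D @ beta)) / (20 - 5)
        )

    def test_rank_deficient_rejected(self, rng):
        X = rng.standard_normal((5, 6))
        with pytest.raises(ModelError, match="penalized"):
            fit_ols_node(DataMatrix(X), 0)

    def test_constant_column_rejected(self, rng):
        X = rng.standard_normal((30, 3))
        X[:, 2] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_ols_node(DataMatrix(X), 0)


class TestLassoNode:
    def test_above_lambda_max_all_zero(self, rng):
        X = rng.standard_normal((60, 5))
        fit = fit_lasso_node(DataMatrix(X), 0, lam=10.0)
        assert np.all(fit.coefficients == 0.0)
        assert fit.selected == []

    def test_orthonormal_soft_threshold(self, rng):
        # orthonormal design: lasso = soft-thresholded OLS, in closed form
        n = 64
        Q, _ = np.linalg.qr(rng.standard_normal((n, 5)))
        X = Q * np.sqrt(n)  # columns: norm^2 = n
        y = X @ np.array([0.9, -0.4, 0.15, 0.0, 0.0]) + 0.1 * rng.standard_normal(n)
        y -= y.mean()
        lam = 0.2
        coef = lasso_fixed(X, y, lam)
        ols = X.T @ y / n
        soft = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
        assert np.allclose(coef, soft, atol=1e-6)

    def test_strong_edge_always_selected(self, fig2):
        # the rho=0.9 partner must enter the CV-selected neighborhood at n=1000
        hits = 0
        for seed in range(20):
            data = sample_gaussian(fig2, 1000, seed=seed)
            fit = fit_lasso_node(data, 16, seed=seed)
            hits += 17 in fit.selected
        assert hits >= 19 * 20 // 20  # >= 95% of runs

    def test_lambda_zero_matches_ols(self, small_data):
        _, data = small_data
        ols = fit_ols_node(data, 0)
        lasso = fit_lasso_node(data, 0, lam=1e-8)
        assert np.max(np.abs(ols.coefficients - lasso.coefficients)) < 1e-4


class TestThresholdLasso:
    def test_zero_and_infinite_threshold(self, small_data):
        _, data = small_data
        fit = fit_lasso_node(data, 0, seed=0)
        same = threshold_lasso(fit, data, threshold=0.0)
        assert np.array_equal(same.coefficients, fit.coefficients)
        empty = threshold_lasso(fit, data, threshold=np.inf)
        assert empty.selected == []

    def test_selection_monotone_in_threshold(self, small_data):
        _, data = small_data
        fit = fit_lasso_node(data, 0, seed=0)
        prev = None
        for thr in [0.0, 0.05, 0.1, 0.3, 1.0]:
            sel = set(threshold_lasso(fit, data, threshold=thr).selected)
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_negative_threshold_rejected(self, small_data):
        _, data = small_data
        fit = fit_lasso_node(data, 0, seed=0)
        with pytest.raises(ValueError):
            threshold_lasso(fit, data, threshold=-0.1)


class TestFitNetwork:
    def test_and_subset_of_or(self, small_data):
        _, data = small_data
        net_and = fit_network(data, method="lasso", rule="and", seed=3)
        net_or = fit_network(data, method="lasso", rule="or", seed=3)
        assert net_and.edge_set() <= net_or.edge_set()

    def test_chain_screening(self):
        # p=4 chain at large n: the CV lasso is prediction-optimal, not
        # selection-consistent, so expect the screening property (no true edge
        # missed) rather than exact support recovery; thresholding can only
        # remove edges
        model = _chain_model()
        truth = model.edge_set()
        screened = 0
        for seed in range(10):
            data = sample_gaussian(model, 3000, seed=seed)
            plain = fit_network(data, method="lasso", rule="and", seed=seed)
            thresh = fit_network(data, method="lasso_thresholded", rule="and",
                                 seed=seed)
            screened += truth <= plain.edge_set()
            assert thresh.edge_set() <= plain.edge_set()
        assert screened >= 9

    def test_null_model_empty_after_thresholding(self):
        model = PrecisionModel(np.eye(6))
        hits = []
        for seed in range(5):
            data = sample_gaussian(model, 2000, seed=seed)
            net = fit_network(data, method="lasso_thresholded", rule="and", seed=seed)
            hits.append(len(net.edge_set()))
        assert np.mean(hits) <= 1.0

    def test_rho_symmetric_for_ols(self, small_data):
        # rho_ij^2 = beta_ij * beta_ji holds exactly for OLS either direction
        _, data = small_data
        net = fit_network(data, method="ols")
        assert np.allclose(net.rho, net.rho.T, atol=1e-12)
        prod = net.beta * net.beta.T
        assert np.allclose(net.rho**2, np.clip(prod, 0, None) * (net.rho != 0),
                           atol=1e-10)


class TestGlassoEbic:
    def test_identity_covariance_gives_diagonal(self, rng):
        X = rng.standard_normal((400, 5))
        fit = glasso_ebic(DataMatrix(X))
        assert fit.adjacency.sum() <= 2  # essentially empty

    def test_gamma_zero_is_bic(self, rng):
        theta = np.eye(4)
        theta[0, 1] = theta[1, 0] = -0.3
        S = np.linalg.inv(theta)
        n = 100
        score = ebic_score(S, theta, n, gamma=0.0)
        sign, logdet = np.linalg.slogdet(theta)
        bic = -n * (logdet - np.trace(S @ theta)) + 1 * np.log(n)
        assert score == pytest.approx(bic)

    def test_recovers_half_the_truth_easily(self):
        from ggminfer.simulate import generate_precision, generate_random_graph

        sens = []
        for seed in range(3):
            adj = generate_random_graph(20, 0.2, seed=seed)
            model = generate_precision(adj, seed=seed)
            data = sample_gaussian(model, 1000, seed=seed)
            fit = glasso_ebic(data)
            truth = model.edge_set()
            est = {
                (i, j)
                for i in range(20) for j in range(i + 1, 20)
                if fit.adjacency[i, j]
            }
            sens.append(len(est & truth) / len(truth))
        assert np.mean(sens) > 0.5
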