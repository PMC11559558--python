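"""Algebraic relations between precision matrices, regressions and partial correlations."""

import numpy as np
import pytest

from ggminfer import (
    DataMatrix,
    EdgeInference,
    ModelError,
    PrecisionModel,
    beta_from_precision,
    partial_cor_from_precision,
    symmetrize_and_rule,
)
from tests.conftest import random_pd_precision


class TestBetaFromPrecision:
    def test_direct_arithmetic(self):
        theta = np.array([[2.0, -0.5], [-0.5, 2.0]])
        assert beta_from_precision(theta, 0, 1) == pytest.approx(0.25)

    def test_identity_gives_zero(self):
        theta = np.eye(4)
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert beta_from_precision(theta, i, j) == 0.0

    def test_non_pd_rejected(self):
        theta = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues -1, 3
        with pytest.raises(ModelError):
            beta_from_precision(theta, 0, 1)

    def test_matches_population_regression_slope(self, rng):
        # oracle: OLS slope of X_0 on the others computed on a huge sample
        theta = random_pd_precision(4, rng)
        model = PrecisionModel(theta)
        n = 1_000_000
        X = rng.standard_normal((n, 4)) @ np.linalg.cholesky(model.sigma).T
        D, y = X[:, 1:], X[:, 0]
        slope = np.linalg.lstsq(D - D.mean(0), y - y.mean(), rcond=None)[0]
        se = np.sqrt(np.diag(np.linalg.inv(D.T @ D))) * y.std()
        for k, j in enumerate([1, 2, 3]):
            beta = beta_from_precision(theta, 0, j)
            assert abs(beta - slope[k]) < 3 * se[k]


class TestPartialCorrelations:
    def test_two_by_two(self):
        theta = np.array([[1.0, -0.3], [-0.3, 1.0]])
        rho = partial_cor_from_precision(theta)
        assert rho[0, 1] == pytest.approx(0.3)
        assert rho[0, 0] == 1.0

    def test_identity(self):
        rho = partial_cor_from_precision(np.eye(5))
        assert np.allclose(rho, np.eye(5))

    def test_matches_residual_correlation_oracle(self):
        # regress out X3 from X1 and X2 using population coefficients and
        # correlate the residuals; pure covariance algebra, no sampling
        sigma = np.array([[2.0, 0.8, 0.5],
                          [0.8, 1.5, 0.6],
                          [0.5, 0.6, 1.2]])
        theta = np.linalg.inv(sigma)
        a = sigma[0, 2] / sigma[2, 2]
        b = sigma[1, 2] / sigma[2, 2]
        cov_resid = sigma[0, 1] - a * sigma[2, 1]
        var1 = sigma[0, 0] - a * sigma[0, 2]
        var2 = sigma[1, 1] - b * sigma[1, 2]
        expected = cov_resid / np.sqrt(var1 * var2)
        rho = partial_cor_from_precision(theta)
        assert rho[0, 1] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_rho_squared_identity_and_bounds(self, seed):
        # rho_ij^2 == beta_ij * beta_ji for every pair of any PD precision
        rng = np.random.default_rng(seed)
        theta = random_pd_precision(6, rng)
        rho = partial_cor_from_precision(theta)
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                assert abs(rho[i, j]) < 1.0
                bij = beta_from_precision(theta, i, j)
                bji = beta_from_precision(theta, j, i)
                assert rho[i, j] ** 2 == pytest.approx(bij * bji, abs=1e-12)
                assert np.sign(rho[i, j]) == np.sign(-theta[i, j])


class TestPrecisionModel:
    def test_invariants(self, rng):
        model = PrecisionModel(random_pd_precision(5, rng))
        assert np.allclose(model.theta @ model.sigma, np.eye(5), atol=1e-8)
        offdiag = model.theta[~np.eye(5, dtype=bool)]
        assert np.array_equal(
            model.adjacency[~np.eye(5, dtype=bool)], (np.abs(offdiag) > 1e-12)
        )

    def test_asymmetric_rejected(self):
        theta = np.eye(3)
        theta[0, 1] = 0.2
        with pytest.raises(ModelError):
            PrecisionModel(theta)

    def test_edgelist_matches_edge_set(self, rng):
        model = PrecisionModel(random_pd_precision(5, rng))
        el = model.to_edgelist(names=list("abcde"))
        assert len(el) == model.n_edges()


class TestDataMatrix:
    def test_validation_errors(self):
        with pytest.raises(ValueError, match="non-finite"):
            DataMatrix(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(ValueError, match="unique"):
            DataMatrix(np.ones((3, 2)), names=("a", "a"))
        with pytest.raises(ValueError, match="at least 2"):
            DataMatrix(np.ones((1, 3)))

    def test_dataframe_round_trip(self, rng):
        dm = DataMatrix(rng.standard_normal((4, 3)), names=("x", "y", "z"))
        assert DataMatrix.from_dataframe(dm.to_dataframe()).names == dm.names


def _edge(i, j, p_corr, estimate=0.5):
    return EdgeInference(i=i, j=j, estimate=estimate, se=0.1, p_raw=p_corr,
                         p_corrected=p_corr, ci_lower=0.0, ci_upper=1.0,
                         significant=p_corr <= 0.05)


class TestAndRule:
    def test_both_significant_keeps_edge(self):
        out = symmetrize_and_rule(_edge(0, 1, 0.01), _edge(1, 0, 0.02), alpha=0.05)
        assert out["significant"]

    def test_one_significant_drops_edge(self):
        out = symmetrize_and_rule(_edge(0, 1, 0.01), _edge(1, 0, 0.2), alpha=0.05)
        assert not out["significant"]
        # the or-rule keeps it
        out_or = symmetrize_and_rule(_edge(0, 1, 0.01), _edge(1, 0, 0.2),
                                     alpha=0.05, rule="or")
        assert out_or["significant"]

    def test_order_invariant(self):
        a, b = _edge(0, 1, 0.01, 0.4), _edge(1, 0, 0.2, 0.6)
        assert symmetrize_and_rule(a, b, 0.05) == symmetrize_and_rule(b, a, 0.05)

    def test_mismatched_pair_rejected(self):
        with pytest.raises(ValueError, match="unordered pair"):
            symmetrize_and_rule(_edge(0, 1, 0.01), _edge(2, 0, 0.01), alpha=0.05)

    def test_and_rule_subset_of_or_rule(self, rng):
        # enumeration over random corrected p-values on all pairs of 6 nodes
        and_set, or_set = set(), set()
        for i in range(6):
            for j in range(i + 1, 6):
                pij, pji = rng.random() * 0.2, rng.random() * 0.2
                res_ij, res_ji = _edge(i, j, pij), _edge(j, i, pji)
                if symmetrize_and_rule(res_ij, res_ji, 0.05)["significant"]:
                    and_set.add((i, j))
                if symmetrize_and_rule(res_ij, res_ji, 0.05, rule="or")["significant"]:
                    or_set.add((i, j))
        assert and_set <= or_set

    def test_combined_estimates(self):
        out = symmetrize_and_rule(_edge(0, 1, 0.01, 0.4), _edge(1, 0, 0.01, 0.9),
                                  alpha=0.05)
        assert out["estimate"] == pytest.approx(0.65)
        assert out["estimate_rho"] == pytest.approx(np.sqrt(0.36))
        # sign disagreement zeroes the partial-correlation-scale estimate
        out2 = symmetrize_and_rule(_edge(0, 1, 0.01, 0.4), _edge(1, 0, 0.01, -0.9),
                                   alpha=0.05)
        assert out2["estimate_rho"] == 0.0
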