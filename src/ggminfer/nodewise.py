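"""Nodewise regression estimation of a GGM.

Each node ``X_i`` is regressed on all remaining nodes,

    X_i = sum_{j != i} X_j beta_ij + e_i,

and the p neighborhoods are stitched into a network with the and-rule (edge
kept when both directions select it) or or-rule.  Estimators:

* OLS — unpenalized least squares with t-test standard errors (needs n > p);
* lasso — 10-fold cross-validated penalty on standardized columns, which both
  estimates and selects (some coefficients are exactly zero);
* thresholded lasso — lasso followed by zeroing coefficients smaller than a
  threshold (default: the CV-chosen penalty itself, on the standardized
  scale).

A graphical-lasso comparator with EBIC penalty selection is also provided; it
penalizes the precision matrix globally rather than nodewise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.covariance import graphical_lasso

from . import _lasso
from .core import DataMatrix, ModelError

__all__ = [
    "NodewiseFit",
    "NetworkFit",
    "fit_ols_node",
    "fit_lasso_node",
    "threshold_lasso",
    "fit_network",
    "glasso_ebic",
    "GlassoFit",
]


@dataclass
class NodewiseFit:
    """One nodewise regression: node ``node`` on the p-1 remaining columns.

    ``coefficients`` are on the original data scale, aligned with
    ``predictors`` (column indices into the data matrix);
    ``coefficients_std`` are on the standardized (unit-variance) scale the
    penalty acts on.  ``selected`` is the set of predictor column indices with
    nonzero coefficient.  ``lam`` is 0 for OLS.
    """

    node: int
    predictors: list[int]
    coefficients: np.ndarray
    coefficients_std: np.ndarray
    residuals: np.ndarray
    sigma2_hat: float
    lam: float
    selected: list[int]
    se: np.ndarray | None = None  # per-coefficient SEs (OLS only)
    df_resid: int | None = None

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _split_design(data: DataMatrix, node: int) -> tuple[np.ndarray, np.ndarray, list[int]]:
    if not 0 <= node < data.p:
        raise ValueError(f"node {node} outside 0..{data.p - 1}")
    X = data.centered()
    predictors = [k for k in range(data.p) if k != node]
    return X[:, predictors], X[:, node], predictors


def fit_ols_node(data: DataMatrix, node: int) -> NodewiseFit:
    """Unpenalized least-squares nodewise fit with classical standard errors."""
    if data.n <= data.p:
        raise ModelError(
            f"OLS needs n > p (got n={data.n}, p={data.p}); use a penalized method"
        )
    D, y, predictors = _split_design(data, node)
    sd = D.std(axis=0)
    if np.any(sd < 1e-12):
        bad = predictors[int(np.argmin(sd))]
        raise ValueError(f"column {bad} is constant; drop it before fitting")
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    df = data.n - data.p  # p-1 coefficients + centering
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(D.T @ D)))
    return NodewiseFit(
        node=node, predictors=predictors, coefficients=coef,
        coefficients_std=coef * sd / y.std(), residuals=resid, sigma2_hat=sigma2,
        lam=0.0, selected=[predictors[k] for k in np.flatnonzero(coef)],
        se=se, df_resid=df,
    )


def ols_pvalues(fit: NodewiseFit) -> np.ndarray:
    """Two-sided t-test p-values for the coefficients of an OLS nodewise fit."""
    if fit.se is None or fit.df_resid is None:
        raise ValueError("p-values require an OLS fit with standard errors")
    tstat = fit.coefficients / fit.se
    return 2.0 * stats.t.sf(np.abs(tstat), fit.df_resid)


def fit_lasso_node(
    data: DataMatrix,
    node: int,
    folds: int = 10,
    seed: int | None = None,
    n_alphas: int = 100,
    eps: float = 1e-4,
    lam: float | None = None,
) -> NodewiseFit:
    """Lasso nodewise fit with 10-fold cross-validated penalty.

    Columns are standardized to unit variance before the penalized fit and
    coefficients are reported back on the original scale; the penalty (and the
    sparsity pattern) therefore does not depend on the variables' units.  Pass
    ``lam`` to skip cross-validation and fit at a fixed penalty (``lam=0``
    gives the unpenalized least-squares solution).
    """
    if data.n < folds:
        raise ValueError(f"need n >= folds (got n={data.n}, folds={folds})")
    D, y, predictors = _split_design(data, node)
    sd = D.std(axis=0)
    if np.any(sd < 1e-12):
        bad = predictors[int(np.argmin(sd))]
        raise ValueError(f"column {bad} is constant; drop it before fitting")
    ysd = y.std()
    Ds, ys = D / sd, y / ysd
    if lam is None:
        coef_std, lam = _lasso.cv_lasso(Ds, ys, n_alphas=n_alphas, eps=eps,
                                        folds=folds, seed=seed)
    else:
        if lam < 0:
            raise ValueError("penalty must be nonnegative")
        coef_std = _lasso.lasso_fixed(Ds, ys, lam)
    coef = coef_std * ysd / sd
    resid = y - D @ coef
    s_hat = int(np.count_nonzero(coef_std))
    sigma2 = float(resid @ resid) / max(data.n - s_hat, 1)
    return NodewiseFit(
        node=node, predictors=predictors, coefficients=coef,
        coefficients_std=coef_std, residuals=resid, sigma2_hat=sigma2,
        lam=float(lam), selected=[predictors[k] for k in np.flatnonzero(coef_std)],
    )


def threshold_lasso(
    fit: NodewiseFit, data: DataMatrix, threshold: float | None = None
) -> NodewiseFit:
    """Zero out lasso coefficients smaller than ``threshold`` (standardized scale).

    The default threshold is the CV-chosen penalty of the fit itself, so the
    surviving coefficients clear the noise level the cross-validation saw.
    """
    if threshold is None:
        threshold = fit.lam
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    keep = np.abs(fit.coefficients_std) >= threshold
    coef_std = np.where(keep, fit.coefficients_std, 0.0)
    coef = np.where(keep, fit.coefficients, 0.0)
    D, y, predictors = _split_design(data, fit.node)
    resid = y - D @ coef
    s_hat = int(np.count_nonzero(coef_std))
    sigma2 = float(resid @ resid) / max(len(y) - s_hat, 1)
    return replace(
        fit, coefficients=coef, coefficients_std=coef_std, residuals=resid,
        sigma2_hat=sigma2,
        selected=[predictors[k] for k in np.flatnonzero(coef_std)],
    )


@dataclass
class NetworkFit:
    """Stitched nodewise fits: coefficient matrix plus rule-based edge selection.

    ``beta[i, j]`` is the coefficient of ``X_j`` in the regression of ``X_i``;
    ``adjacency`` applies the and/or rule to the nonzero pattern; ``rho`` is
    the sign-consistent geometric mean ``sign(b) * sqrt(b_ij * b_ji)`` on
    edges where both directions are nonzero with agreeing signs, else 0.
    """

    beta: np.ndarray
    adjacency: np.ndarray
    rho: np.ndarray
    rule: str
    method: str
    fits: list[NodewiseFit] = field(repr=False, default_factory=list)

    def edge_set(self) -> set[tuple[int, int]]:
        iu, ju = np.triu_indices(self.adjacency.shape[0], k=1)
        keep = self.adjacency[iu, ju] == 1
        return set(zip(iu[keep].tolist(), ju[keep].tolist()))


def rho_matrix(beta: np.ndarray) -> np.ndarray:
    """Partial-correlation-scale estimates from a nodewise coefficient matrix."""
    prod = beta * beta.T
    same_sign = (np.sign(beta) == np.sign(beta.T)) & (beta != 0.0)
    rho = np.zeros_like(beta)
    rho[same_sign] = np.sign(beta[same_sign]) * np.sqrt(prod[same_sign])
    return rho


def fit_network(
    data: DataMatrix,
    method: str = "lasso",
    rule: str = "and",
    seed: int | None = None,
    threshold: float | None = None,
    folds: int = 10,
) -> NetworkFit:
    """Fit all p nodewise regressions and combine neighborhoods into a network."""
    if rule not in ("and", "or"):
        raise ValueError(f"rule must be 'and' or 'or', got {rule!r}")
    if method not in ("ols", "lasso", "lasso_thresholded"):
        raise ValueError(f"unknown nodewise method {method!r}")
    rng = np.random.default_rng(seed)
    p = data.p
    beta = np.zeros((p, p))
    fits = []
    for node in range(p):
        if method == "ols":
            fit = fit_ols_node(data, node)
        else:
            fit = fit_lasso_node(data, node, folds=folds,
                                 seed=int(rng.integers(2**31)))
            if method == "lasso_thresholded":
                fit = threshold_lasso(fit, data, threshold)
        beta[node, fit.predictors] = fit.coefficients
        fits.append(fit)
    nonzero = beta != 0.0
    if rule == "and":
        adjacency = (nonzero & nonzero.T).astype(int)
    else:
        adjacency = (nonzero | nonzero.T).astype(int)
    return NetworkFit(beta=beta, adjacency=adjacency, rho=rho_matrix(beta),
                      rule=rule, method=method, fits=fits)


@dataclass
class GlassoFit:
    """Graphical-lasso comparator output."""

    precision: np.ndarray
    adjacency: np.ndarray
    lam: float
    gamma: float
    ebic_path: list[tuple[float, float]]
    failures: int

    @property
    def rho(self) -> np.ndarray:
        d = 1.0 / np.sqrt(np.diag(self.precision))
        rho = -self.precision * np.outer(d, d)
        np.fill_diagonal(rho, 0.0)
        return rho


def ebic_score(S: np.ndarray, theta: np.ndarray, n: int, gamma: float) -> float:
    """Extended BIC for a Gaussian log-likelihood with edge count penalty.

    ``EBIC = -n(logdet Theta - tr(S Theta)) + E ln n + 4 gamma E ln p`` with
    ``E`` the number of nonzero upper-triangle entries; ``gamma=0`` recovers
    the ordinary BIC.
    """
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    loglik = n * (logdet - np.trace(S @ theta))
    E = int(np.count_nonzero(np.triu(theta, k=1)))
    return float(-loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p))


def glasso_ebic(
    data: DataMatrix,
    gamma: float = 0.5,
    n_lambdas: int = 30,
    eps: float = 1e-2,
) -> GlassoFit:
    """Graphical lasso with the regularization path scored by EBIC(gamma).

    Fits on the correlation matrix over a log-spaced penalty grid from the
    smallest penalty that empties the graph down to ``eps`` times it; solver
    failures at individual penalties are counted and skipped rather than
    raised.
    """
    X = data.centered()
    S = np.corrcoef(X, rowvar=False)
    lam_max = float(np.max(np.abs(S - np.eye(data.p))))
    grid = np.geomspace(lam_max, eps * lam_max, n_lambdas)
    best = None
    path: list[tuple[float, float]] = []
    failures = 0
    for lam in grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, theta = graphical_lasso(S, alpha=float(lam), max_iter=200)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            failures += 1
            continue
        score = ebic_score(S, theta, data.n, gamma)
        path.append((float(lam), score))
        if best is None or score < best[1]:
            best = (float(lam), score, theta)
    if best is None:
        raise ModelError("graphical lasso failed to converge at every penalty")
    lam, _, theta = best
    adjacency = (np.abs(theta) > 1e-8).astype(int)
    np.fill_diagonal(adjacency, 0)
    return GlassoFit(precision=theta, adjacency=adjacency, lam=lam, gamma=gamma,
                     ebic_path=path, failures=failures)
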