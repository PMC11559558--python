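"""Core data model for Gaussian graphical models (GGMs).

A GGM couples an undirected graph with a multivariate normal distribution:
an absent edge between nodes ``i`` and ``j`` means the variables ``X_i`` and
``X_j`` are conditionally independent given all remaining variables, which for
Gaussian data is equivalent to a zero entry ``Theta_ij`` in the precision
(inverse covariance) matrix.  This module houses the exact algebraic relations
between the precision matrix, the nodewise-regression coefficients

    beta_ij = -Theta_ij / Theta_ii

and the partial correlations

    rho_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj),

together with the containers the rest of the package passes around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelError",
    "PrecisionModel",
    "DataMatrix",
    "EdgeInference",
    "beta_from_precision",
    "partial_cor_from_precision",
    "symmetrize_and_rule",
]


class ModelError(ValueError):
    """Raised when a matrix does not define a valid Gaussian graphical model."""


_SYM_TOL = 1e-10
_SUPPORT_TOL = 1e-12


def _validate_precision(theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
        raise ModelError(f"precision matrix must be square, got shape {theta.shape}")
    if not np.allclose(theta, theta.T, atol=_SYM_TOL, rtol=0.0):
        raise ModelError("precision matrix is not symmetric (tolerance 1e-10)")
    eigmin = float(np.linalg.eigvalsh(theta)[0])
    if eigmin <= 0.0:
        raise ModelError(
            f"precision matrix is not positive definite (min eigenvalue {eigmin:.3e})"
        )
    return theta


def beta_from_precision(theta: np.ndarray, i: int, j: int) -> float:
    """Nodewise regression coefficient implied by a precision matrix.

    Regressing ``X_i`` on the remaining variables, the population coefficient
    of ``X_j`` is ``beta_ij = -Theta_ij / Theta_ii``; it is zero exactly when
    the partial covariance ``Theta_ij`` is zero.
    """
    theta = _validate_precision(theta)
    if i == j:
        raise ValueError("beta_ij is defined for i != j only")
    return float(-theta[i, j] / theta[i, i])


def partial_cor_from_precision(theta: np.ndarray) -> np.ndarray:
    """Partial correlation matrix ``rho_ij = -Theta_ij / sqrt(Theta_ii Theta_jj)``.

    The diagonal is set to 1 by convention.  Off-diagonal entries of a valid
    precision matrix always lie strictly inside (-1, 1).
    """
    theta = _validate_precision(theta)
    d = 1.0 / np.sqrt(np.diag(theta))
    rho = -theta * np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


@dataclass(frozen=True)
class PrecisionModel:
    """Ground-truth GGM: graph + precision matrix + implied quantities.

    Parameters
    ----------
    theta
        Symmetric positive-definite precision matrix (p x p).

    Attributes derived on construction: ``sigma`` (the covariance
    ``Theta^{-1}``), ``adjacency`` (binary support of the off-diagonal of
    ``theta``), ``partial_correlations`` and the nodewise ``beta`` matrix with
    ``beta[i, j] = -theta[i, j] / theta[i, i]``.
    """

    theta: np.ndarray
    sigma: np.ndarray = field(init=False, repr=False)
    adjacency: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        theta = _validate_precision(self.theta)
        object.__setattr__(self, "theta", theta)
        sigma = np.linalg.inv(theta)
        if not np.allclose(theta @ sigma, np.eye(theta.shape[0]), atol=1e-8):
            raise ModelError("theta is numerically singular: theta @ inv(theta) != I")
        object.__setattr__(self, "sigma", sigma)
        adj = (np.abs(theta) > _SUPPORT_TOL).astype(int)
        np.fill_diagonal(adj, 0)
        object.__setattr__(self, "adjacency", adj)

    @property
    def p(self) -> int:
        return self.theta.shape[0]

    @property
    def partial_correlations(self) -> np.ndarray:
        return partial_cor_from_precision(self.theta)

    @property
    def beta(self) -> np.ndarray:
        """Matrix of population nodewise coefficients, ``beta[i, j] = beta_ij``."""
        b = -self.theta / np.diag(self.theta)[:, None]
        np.fill_diagonal(b, 0.0)
        return b

    def edge_set(self) -> set[tuple[int, int]]:
        """True edges as unordered pairs ``(i, j)`` with ``i < j``."""
        iu, ju = np.triu_indices(self.p, k=1)
        keep = self.adjacency[iu, ju] == 1
        return set(zip(iu[keep].tolist(), ju[keep].tolist()))

    def n_edges(self) -> int:
        return len(self.edge_set())

    def to_edgelist(self, names: list[str] | None = None) -> pd.DataFrame:
        """Truth as a tidy edge list (i, j, theta_ij, rho_ij)."""
        names = names or [f"X{k + 1}" for k in range(self.p)]
        rho = self.partial_correlations
        rows = [
            {"i": names[i], "j": names[j], "theta_ij": self.theta[i, j], "rho_ij": rho[i, j]}
            for i, j in sorted(self.edge_set())
        ]
        return pd.DataFrame(rows, columns=["i", "j", "theta_ij", "rho_ij"])


@dataclass(frozen=True)
class DataMatrix:
    """An n x p observation matrix with unique variable names."""

    values: np.ndarray
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("data must be a 2-D matrix of observations x variables")
        n, p = values.shape
        if n < 2 or p < 2:
            raise ValueError(f"need at least 2 rows and 2 columns, got {n} x {p}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at row {bad[0] + 1}, column {bad[1] + 1}"
            )
        names = tuple(self.names) if self.names else tuple(f"X{k + 1}" for k in range(p))
        if len(names) != p:
            raise ValueError(f"{len(names)} names for {p} columns")
        if len(set(names)) != p:
            raise ValueError("variable names must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DataMatrix":
        return cls(df.to_numpy(dtype=float), tuple(str(c) for c in df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))

    def centered(self) -> np.ndarray:
        """Column-centered copy of the values (all fits center, no intercept)."""
        return self.values - self.values.mean(axis=0)


@dataclass
class EdgeInference:
    """Inference for one ordered edge: regression of node ``i`` on node ``j``."""

    i: int
    j: int
    estimate: float
    se: float
    p_raw: float
    p_corrected: float
    ci_lower: float
    ci_upper: float
    significant: bool
    scale: str = "beta"  # 'beta' (regression coefficient) or 'rho' (partial correlation)

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_lower) and np.isfinite(self.ci_upper):
            if self.ci_lower > self.ci_upper:
                raise ValueError("ci_lower > ci_upper")
        for name in ("p_raw", "p_corrected"):
            v = getattr(self, name)
            if np.isfinite(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def _rho_from_pair(b_ij: float, b_ji: float) -> float:
    # sign-consistent geometric mean; 0 when the two directions disagree in sign
    if b_ij == 0.0 or b_ji == 0.0 or np.sign(b_ij) != np.sign(b_ji):
        return 0.0
    return float(np.sign(b_ij) * np.sqrt(b_ij * b_ji))


def symmetrize_and_rule(
    result_ij: EdgeInference,
    result_ji: EdgeInference,
    alpha: float,
    rule: str = "and",
) -> dict:
    """Combine the two ordered results for one unordered pair into an edge decision.

    Under the *and*-rule the edge is kept only when **both** ordered tests are
    significant after correction; the *or*-rule keeps it when either is.  The
    combined coefficient-scale estimate is the arithmetic mean of the two
    directions; the partial-correlation-scale estimate is the sign-consistent
    geometric mean ``sign(b_ij) * sqrt(b_ij * b_ji)`` (0 when signs disagree).
    """
    if {result_ij.i, result_ij.j} != {result_ji.i, result_ji.j}:
        raise ValueError("results do not refer to the same unordered pair")
    if rule not in ("and", "or"):
        raise ValueError(f"rule must be 'and' or 'or', got {rule!r}")
    sig_ij = result_ij.p_corrected <= alpha
    sig_ji = result_ji.p_corrected <= alpha
    significant = (sig_ij and sig_ji) if rule == "and" else (sig_ij or sig_ji)
    return {
        "i": min(result_ij.i, result_ij.j),
        "j": max(result_ij.i, result_ij.j),
        "significant": bool(significant),
        "estimate": 0.5 * (result_ij.estimate + result_ji.estimate),
        "estimate_rho": _rho_from_pair(result_ij.estimate, result_ji.estimate),
    }
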