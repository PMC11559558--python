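"""Synthetic GGM generation and assumption diagnostics.

Simulation truths are built in three steps: an Erdos-Renyi style random graph
(each of the p(p-1)/2 unordered pairs present independently with probability
``pe``), uniform edge weights on the support, and a positive-definiteness
repair.  The repair adds ``|lambda_min| + 0.1`` to the diagonal and rescales
to unit diagonal, so off-diagonal entries of the resulting precision matrix
are (up to sign) the model's partial correlations and the support of the
graph is preserved exactly.

The module also provides the lasso assumption heuristics used to place the
simulation conditions relative to the sparsity and beta-min assumptions:

* ``sparsity_allowance(n, p) = floor(sqrt(n / ln p))`` — the largest
  neighborhood size the sample can support;
* ``beta_min_heuristic(n, p) = sqrt(ln p / n)`` — the smallest coefficient
  magnitude the lasso can reliably detect.

All randomness flows from a single integer seed through numpy's default
``Generator`` (PCG64), so every artifact is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DataMatrix, PrecisionModel

__all__ = [
    "SimulationDesign",
    "generate_random_graph",
    "generate_precision",
    "sample_gaussian",
    "simulate_dataset",
    "sparsity_allowance",
    "beta_min_heuristic",
    "fraction_above_betamin",
    "count_sparsity_violations",
    "fig2_model",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the simulation grid."""

    p: int = 20
    pe: float = 0.2
    n: int = 500
    weight_low: float = 0.1
    weight_high: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pe <= 1.0:
            raise ValueError(f"pe={self.pe} outside [0, 1]")
        if not 0.0 < self.weight_low < self.weight_high:
            raise ValueError("need 0 < weight_low < weight_high")


def generate_random_graph(p: int, pe: float, seed=None) -> np.ndarray:
    """Symmetric binary adjacency matrix with independent edges of probability ``pe``."""
    if p < 2:
        raise ValueError("need p >= 2 nodes")
    if not 0.0 <= pe <= 1.0:
        raise ValueError(f"edge probability pe={pe} outside [0, 1]")
    rng = _rng(seed)
    upper = np.triu(rng.random((p, p)) < pe, k=1).astype(int)
    return upper + upper.T


def generate_precision(
    adjacency: np.ndarray,
    weight_low: float = 0.1,
    weight_high: float = 0.8,
    seed=None,
) -> PrecisionModel:
    """Sparse positive-definite precision matrix on a given support.

    Off-diagonal magnitudes are drawn Uniform(weight_low, weight_high), all
    positive partial covariances omitted sign-flips (entries are negative in
    Theta so that the implied partial correlations are positive).  The matrix
    is made positive definite by diagonal loading and rescaled to unit
    diagonal, which preserves the support and makes ``-Theta_ij`` equal to the
    model's partial correlation.
    """
    adjacency = np.asarray(adjacency)
    if not np.array_equal(adjacency, adjacency.T) or np.any(np.diag(adjacency) != 0):
        raise ValueError("adjacency must be symmetric with zero diagonal")
    rng = _rng(seed)
    p = adjacency.shape[0]
    upper = np.triu(adjacency, k=1).astype(float)
    weights = rng.uniform(weight_low, weight_high, size=(p, p))
    theta0 = -(upper * weights)
    theta0 = theta0 + theta0.T
    eigmin = float(np.linalg.eigvalsh(theta0)[0])
    theta = theta0 + (abs(eigmin) + 0.1) * np.eye(p)
    d = 1.0 / np.sqrt(np.diag(theta))
    theta = theta * np.outer(d, d)
    theta = 0.5 * (theta + theta.T)  # keep exact symmetry after rescaling
    return PrecisionModel(theta)


def sample_gaussian(model: PrecisionModel, n: int, seed=None) -> DataMatrix:
    """Draw ``n`` i.i.d. rows from N(0, Sigma) with ``Sigma = Theta^{-1}``."""
    if n < 2:
        raise ValueError("need n >= 2 observations")
    rng = _rng(seed)
    chol = np.linalg.cholesky(model.sigma)
    values = rng.standard_normal((n, model.p)) @ chol.T
    return DataMatrix(values)


def simulate_dataset(design: SimulationDesign, seed=None) -> tuple[PrecisionModel, DataMatrix]:
    """Truth and data for one simulation cell, reproducible from one seed."""
    rng = _rng(design.seed if seed is None else seed)
    adj = generate_random_graph(design.p, design.pe, rng)
    model = generate_precision(adj, design.weight_low, design.weight_high, rng)
    data = sample_gaussian(model, design.n, rng)
    return model, data


def sparsity_allowance(n: int, p: int) -> int:
    """Largest neighborhood size supported at sample size ``n`` with ``p`` nodes.

    Returns ``floor(sqrt(n / ln p))``: about 4 at (n=50, p=20) and about 12 at
    (n=500, p=20).
    """
    if n < 2 or p < 2:
        raise ValueError("need n >= 2 and p >= 2")
    return int(math.floor(math.sqrt(n / math.log(p))))


def beta_min_heuristic(n: int, p: int) -> float:
    """Detectability floor for nodewise coefficients: ``sqrt(ln p / n)``.

    About 0.25 at (n=50, p=20) and about 0.08 at (n=500, p=20); true
    coefficients below this value cannot be reliably selected by the lasso.
    """
    if n < 2 or p < 2:
        raise ValueError("need n >= 2 and p >= 2")
    return math.sqrt(math.log(p) / n)


def fraction_above_betamin(weight_low: float, weight_high: float, d: float) -> float:
    """Fraction of Uniform(weight_low, weight_high) edge weights exceeding ``d``."""
    if not weight_low < weight_high:
        raise ValueError("need weight_low < weight_high")
    frac = (weight_high - d) / (weight_high - weight_low)
    return float(min(1.0, max(0.0, frac)))


def count_sparsity_violations(adjacency: np.ndarray, s: int) -> int:
    """Number of nodes whose degree exceeds the sparsity allowance ``s``."""
    adjacency = np.asarray(adjacency)
    degrees = adjacency.sum(axis=1)
    return int(np.sum(degrees > s))


def fig2_model() -> PrecisionModel:
    """20-node GGM with nine nonzero partial correlations 0.1, 0.2, ..., 0.9.

    The nine edges sit on vertex-disjoint pairs (0,1)=0.1, (2,3)=0.2, ...,
    (16,17)=0.9, with nodes 18 and 19 isolated.  The precision matrix has unit
    diagonal and ``Theta_{2k, 2k+1} = -rho_k``, so each 2x2 block inverts in
    closed form and the implied partial correlations are exact.
    """
    p = 20
    theta = np.eye(p)
    for k in range(9):
        rho = (k + 1) / 10.0
        theta[2 * k, 2 * k + 1] = theta[2 * k + 1, 2 * k] = -rho
    return PrecisionModel(theta)
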