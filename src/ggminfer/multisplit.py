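"""Multi sample-split p-values for network edges.

The single-split procedure sidesteps the lasso's broken sampling distribution
with a two-stage design: (1) split the sample into halves N1/N2; (2) select
each node's neighborhood with the cross-validated lasso on N1; (3) compute
ordinary OLS t-test p-values on N2, restricted to the selected edges, with
p = 1 for everything unselected; (4) correct each node's p-values by its
selected-set size |S1| (a much smaller multiplicity factor than the full
p(p-1) family).  Selection and testing use disjoint data, so the second-stage
p-values are ordinary ones.

A single split is arbitrary — another split gives other p-values — so the
procedure is repeated K times and the K p-values per edge are aggregated
through an empirical-quantile rule: with gamma ranging over [gamma_min, 1],

    Q(gamma)  = min{1, gamma-quantile of {p_k / gamma}}
    p_final   = min{1, (1 - ln gamma_min) * min_gamma Q(gamma)}.

The aggregated p-value embeds its own multiplicity control; no further Holm
pass is applied.  The method emits p-values only — its confidence intervals
are known to undercover, which is documented rather than patched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataMatrix
from .inference import edge_table, pair_table
from .nodewise import fit_lasso_node

__all__ = [
    "SplitResult",
    "single_split",
    "aggregate_multisplit",
    "multisplit_network",
    "MultisplitNetwork",
]


@dataclass
class SplitResult:
    """One half-split: per-node selections and second-half corrected p-values."""

    split_index: int
    n1: int
    n2: int
    selected: dict[int, list[int]]          # node -> selected predictor columns
    pvalues: dict[tuple[int, int], float]   # ordered edge -> corrected p (1 if unselected)
    estimates: dict[tuple[int, int], float]  # N2-OLS coefficients for selected edges


def single_split(
    data: DataMatrix,
    seed: int | None = None,
    folds: int = 10,
    split_index: int = 0,
) -> SplitResult:
    """Lasso selection on one half, per-node-corrected OLS p-values on the other."""
    if data.n < 20:
        raise ValueError(f"sample splitting needs n >= 20 (got n={data.n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n)
    n1 = data.n // 2
    rows1, rows2 = perm[:n1], perm[n1:]
    d1 = DataMatrix(data.values[rows1], data.names)
    X2 = data.values[rows2] - data.values[rows2].mean(axis=0)
    n2 = len(rows2)

    selected: dict[int, list[int]] = {}
    pvalues: dict[tuple[int, int], float] = {}
    estimates: dict[tuple[int, int], float] = {}
    for node in range(data.p):
        fit = fit_lasso_node(d1, node, folds=folds, seed=int(rng.integers(2**31)))
        sel = list(fit.selected)
        if len(sel) >= n2:
            # second half cannot identify this many coefficients
            warnings.warn(
                f"node {node}: {len(sel)} selected but n2={n2}; "
                f"keeping the {n2 - 1} largest |coefficient|", stacklevel=2,
            )
            mags = {
                pred: abs(fit.coefficients_std[k])
                for k, pred in enumerate(fit.predictors) if pred in sel
            }
            sel = sorted(sorted(sel, key=lambda q: -mags[q])[: n2 - 1])
        selected[node] = sel
        for other in range(data.p):
            if other != node:
                pvalues[(node, other)] = 1.0
        if not sel:
            continue
        D = X2[:, sel]
        y = X2[:, node]
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ coef
        df = n2 - len(sel) - 1  # centering absorbs the intercept
        if df < 1:
            df = 1
        sigma2 = float(resid @ resid) / df
        se = np.sqrt(sigma2 * np.diag(np.linalg.pinv(D.T @ D)))
        praw = 2.0 * stats.t.sf(np.abs(coef / se), df)
        for k, pred in enumerate(sel):
            pvalues[(node, pred)] = float(min(1.0, praw[k] * len(sel)))
            estimates[(node, pred)] = float(coef[k])
    return SplitResult(split_index=split_index, n1=n1, n2=n2,
                       selected=selected, pvalues=pvalues, estimates=estimates)


def aggregate_multisplit(
    splits: list[SplitResult],
    gamma_min: float = 0.05,
    n_gamma: int = 100,
) -> dict[tuple[int, int], float]:
    """Quantile-aggregate the K per-split p-values into one p-value per edge."""
    if len(splits) < 2:
        raise ValueError("aggregation needs at least 2 splits")
    if not 0.0 < gamma_min < 1.0:
        raise ValueError("gamma_min must lie in (0, 1)")
    gammas = np.geomspace(gamma_min, 1.0, n_gamma)
    factor = 1.0 - np.log(gamma_min)
    out: dict[tuple[int, int], float] = {}
    edges = splits[0].pvalues.keys()
    for edge in edges:
        pk = np.array([s.pvalues[edge] for s in splits])
        q = np.minimum(1.0, np.quantile(pk[:, None] / gammas[None, :], gammas,
                                        axis=0).diagonal())
        out[edge] = float(min(1.0, factor * q.min()))
    return out


@dataclass
class MultisplitNetwork:
    """Aggregated multisplit inference: ordered edge table + pair decisions."""

    edges: pd.DataFrame
    pairs: pd.DataFrame
    splits: list[SplitResult]
    alpha: float
    rule: str


def multisplit_network(
    data: DataMatrix,
    K: int = 50,
    alpha: float = 0.05,
    rule: str = "and",
    seed: int | None = None,
    folds: int = 10,
    gamma_min: float = 0.05,
) -> MultisplitNetwork:
    """K random half-splits, aggregated per ordered edge, and-rule symmetrized.

    Estimates are the across-split averages of the second-half OLS
    coefficients on splits where the edge was selected (0 when never
    selected).  No standard errors or CIs are reported: the aggregated
    p-value has no accompanying interval with correct coverage.
    """
    rng = np.random.default_rng(seed)
    splits = [
        single_split(data, seed=int(rng.integers(2**31)), folds=folds, split_index=k)
        for k in range(K)
    ]
    agg = aggregate_multisplit(splits, gamma_min=gamma_min)
    rows = []
    for (i, j), p_final in agg.items():
        ests = [s.estimates[(i, j)] for s in splits if (i, j) in s.estimates]
        rows.append({
            "i": i, "j": j,
            "estimate": float(np.mean(ests)) if ests else 0.0,
            "se": np.nan, "p_raw": p_final, "p_corrected": p_final,
            "ci_lower": np.nan, "ci_upper": np.nan,
        })
    edges = edge_table(rows, data.names, alpha, correct=None)
    pairs = pair_table(edges, alpha, rule=rule)
    return MultisplitNetwork(edges=edges, pairs=pairs, splits=splits,
                             alpha=alpha, rule=rule)
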