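"""Model/Results front end for Gaussian graphical model inference.

Typical use mirrors statsmodels: build a :class:`GGM` from data, call
``fit`` with the method of interest, and read the results object::

    import pandas as pd
    from ggminfer import GGM

    df = pd.read_csv("data.csv")
    res = GGM.from_dataframe(df).fit(method="desplasso", alpha=0.05, seed=1)
    print(res.summary())
    res.plot_ci()

Seven methods are exposed, matching the estimators compared in the package's
simulation engine: ``ols``, ``lasso``, ``lasso_thresholded``, ``desplasso``,
``desplasso_boot``, ``multisplit`` and ``glasso_ebic``.  The inference
methods (ols, desplasso, desplasso_boot, multisplit) return per-edge
p-values, family-wise corrected across all p(p-1) ordered tests, and
and-rule edge decisions; the estimation-only methods return edge selections
without uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference
from .core import DataMatrix
from .nodewise import (
    fit_network,
    fit_ols_node,
    glasso_ebic,
    ols_pvalues,
    rho_matrix,
)

__all__ = ["GGM", "GGMResults"]

_INFERENCE_METHODS = ("ols", "desplasso", "desplasso_boot", "multisplit")
_ESTIMATION_METHODS = ("lasso", "lasso_thresholded", "glasso_ebic")


@dataclass
class GGMResults:
    """Fitted network with edge decisions and (where available) uncertainty.

    Attributes
    ----------
    edge_table
        Ordered p(p-1)-row table (i, j, estimate, se, p_raw, p_corrected,
        ci_lower, ci_upper, significant); ``None`` for estimation-only
        methods.
    pairs
        Unordered pair decisions after rule symmetrization, with combined
        estimates on the coefficient (``estimate``) and partial-correlation
        (``estimate_rho``) scales.
    """

    method: str
    alpha: float
    rule: str
    names: tuple[str, ...]
    pairs: pd.DataFrame
    edge_table: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict, repr=False)

    @property
    def p(self) -> int:
        return len(self.names)

    def edge_set(self) -> set[tuple[int, int]]:
        """Significant (selected) unordered edges."""
        sig = self.pairs[self.pairs["significant"]]
        return set(zip(sig["i"].tolist(), sig["j"].tolist()))

    @property
    def adjacency(self) -> pd.DataFrame:
        adj = np.zeros((self.p, self.p), dtype=int)
        for i, j in self.edge_set():
            adj[i, j] = adj[j, i] = 1
        return pd.DataFrame(adj, index=list(self.names), columns=list(self.names))

    @property
    def estimates(self) -> pd.DataFrame:
        """Symmetric partial-correlation-scale estimate matrix (all pairs)."""
        est = np.zeros((self.p, self.p))
        for _, row in self.pairs.iterrows():
            est[row["i"], row["j"]] = est[row["j"], row["i"]] = row["estimate_rho"]
        return pd.DataFrame(est, index=list(self.names), columns=list(self.names))

    @property
    def significant_estimates(self) -> pd.DataFrame:
        """Estimate matrix with non-significant entries zeroed."""
        return self.estimates * self.adjacency.to_numpy()

    def summary(self) -> str:
        lines = [
            "Gaussian graphical model inference",
            "=" * 58,
            f"method: {self.method:<22} nodes: {self.p}",
            f"alpha (family-wise): {self.alpha:<9} rule: {self.rule}",
            f"ordered tests: {0 if self.edge_table is None else len(self.edge_table):<15}"
            f" significant edges: {len(self.edge_set())}",
            "-" * 58,
        ]
        sig = self.pairs[self.pairs["significant"]]
        if len(sig) == 0:
            lines.append("no significant edges")
        else:
            shown = sig.reindex(
                sig["estimate_rho"].abs().sort_values(ascending=False).index
            )
            lines.append("edge                     rho_hat     beta_hat")
            for _, row in shown.head(20).iterrows():
                lines.append(
                    f"{row['name_i']} -- {row['name_j']:<18} "
                    f"{row['estimate_rho']:>8.3f} {row['estimate']:>12.3f}"
                )
            if len(shown) > 20:
                lines.append(f"... and {len(shown) - 20} more")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_ci(self, subset: int | None = 50, order: bool = True, ax=None):
        """Confidence-interval ladder for the ordered edge estimates.

        Plots each ordered edge's estimate with its CI, optionally sorted by
        decreasing absolute estimate and truncated to the first ``subset``.
        """
        if self.edge_table is None or self.edge_table["ci_lower"].isna().all():
            raise ValueError(f"method {self.method!r} provides no confidence intervals")
        import matplotlib.pyplot as plt

        table = self.edge_table
        if order:
            table = table.reindex(
                table["estimate"].abs().sort_values(ascending=False).index
            )
        if subset:
            table = table.head(subset)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.18 * len(table) + 1))
        ypos = np.arange(len(table))[::-1]
        ax.hlines(ypos, table["ci_lower"], table["ci_upper"], color="0.5")
        ax.plot(table["estimate"], ypos, "o", ms=3,
                color="C0", label="estimate")
        ax.axvline(0.0, color="k", lw=0.8, ls=":")
        ax.set_yticks(ypos)
        ax.set_yticklabels(
            [f"{r['name_i']}~{r['name_j']}" for _, r in table.iterrows()], fontsize=6
        )
        ax.set_xlabel("edge coefficient")
        return ax

    def save(self, directory) -> None:
        """Write the edge table (TSV) and adjacency (CSV) to a directory."""
        from . import io

        io.save_results(self, directory)


class GGM:
    """Gaussian graphical model to be estimated from an n x p data matrix."""

    def __init__(self, data, names=None):
        if isinstance(data, DataMatrix):
            self.data = data
        else:
            self.data = DataMatrix(np.asarray(data, dtype=float),
                                   tuple(names) if names else ())
        self.names = self.data.names

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GGM":
        return cls(DataMatrix.from_dataframe(df))

    @property
    def n(self) -> int:
        return self.data.n

    @property
    def p(self) -> int:
        return self.data.p

    def fit(
        self,
        method: str = "desplasso",
        alpha: float = 0.05,
        rule: str = "and",
        seed: int | None = None,
        **kwargs,
    ) -> GGMResults:
        """Estimate the network and, for inference methods, per-edge uncertainty.

        Extra keyword arguments reach the underlying method (e.g. ``K`` for
        ``multisplit``/``desplasso_boot``, ``threshold`` for
        ``lasso_thresholded``, ``gamma`` for ``glasso_ebic``,
        ``inner='fixed'`` for the desparsified projection penalty).
        """
        if method == "ols":
            return self._fit_ols(alpha, rule)
        if method == "desplasso":
            from .desparsified import despars_network

            net = despars_network(self.data, alpha=alpha, rule=rule, seed=seed,
                                  **kwargs)
            return GGMResults(method=method, alpha=alpha, rule=rule,
                              names=self.names, pairs=net.pairs,
                              edge_table=net.edges, extras={"fits": net.fits})
        if method == "desplasso_boot":
            from .bootstrap import bootstrap_desparsified

            net = bootstrap_desparsified(self.data, alpha=alpha, rule=rule,
                                         seed=seed, **kwargs)
            return GGMResults(method=method, alpha=alpha, rule=rule,
                              names=self.names, pairs=net.pairs,
                              edge_table=net.edges,
                              extras={"samples": net.samples, "K": net.K})
        if method == "multisplit":
            from .multisplit import multisplit_network

            net = multisplit_network(self.data, alpha=alpha, rule=rule,
                                     seed=seed, **kwargs)
            return GGMResults(method=method, alpha=alpha, rule=rule,
                              names=self.names, pairs=net.pairs,
                              edge_table=net.edges,
                              extras={"splits": net.splits})
        if method in ("lasso", "lasso_thresholded"):
            net = fit_network(self.data, method=method, rule=rule, seed=seed,
                              **kwargs)
            return GGMResults(method=method, alpha=alpha, rule=rule,
                              names=self.names,
                              pairs=self._pairs_from_matrices(net.beta, net.adjacency),
                              extras={"fits": net.fits})
        if method == "glasso_ebic":
            fit = glasso_ebic(self.data, **kwargs)
            rho = fit.rho
            return GGMResults(method=method, alpha=alpha, rule=rule,
                              names=self.names,
                              pairs=self._pairs_from_matrices(rho, fit.adjacency,
                                                              rho_given=True),
                              extras={"lam": fit.lam, "failures": fit.failures})
        raise ValueError(
            f"unknown method {method!r}; choose from "
            f"{_INFERENCE_METHODS + _ESTIMATION_METHODS}"
        )

    def _fit_ols(self, alpha: float, rule: str) -> GGMResults:
        rows = []
        for node in range(self.p):
            fit = fit_ols_node(self.data, node)
            pvals = ols_pvalues(fit)
            for k, pred in enumerate(fit.predictors):
                rows.append({
                    "i": node, "j": pred,
                    "estimate": float(fit.coefficients[k]),
                    "se": float(fit.se[k]), "p_raw": float(pvals[k]),
                })
        edges = inference.edge_table(rows, self.names, alpha, correct="holm")
        pairs = inference.pair_table(edges, alpha, rule=rule)
        return GGMResults(method="ols", alpha=alpha, rule=rule,
                          names=self.names, pairs=pairs, edge_table=edges)

    def _pairs_from_matrices(
        self, mat: np.ndarray, adjacency: np.ndarray, rho_given: bool = False
    ) -> pd.DataFrame:
        rho = mat if rho_given else rho_matrix(mat)
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                rows.append({
                    "i": i, "j": j,
                    "name_i": self.names[i], "name_j": self.names[j],
                    "estimate": mat[i, j] if rho_given
                    else 0.5 * (mat[i, j] + mat[j, i]),
                    "estimate_rho": rho[i, j],
                    "significant": bool(adjacency[i, j]),
                })
        return pd.DataFrame(rows)
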