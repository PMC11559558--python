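"""Multiple-testing correction, confidence intervals, and edge-table assembly.

A network with p nodes yields m = p(p-1) ordered tests (every pair in both
regression directions), so family-wise error control matters.  The operational
correction is the Holm step-down procedure (via statsmodels): sort the raw
p-values ascending, multiply the r-th by (m - r + 1), enforce monotonicity
with a running maximum and cap at 1.

``printed_correction_factor`` reproduces, verbatim, a published worked example
whose correction factor is written as ``m - i - j`` (378 for m=380, i=j=1, and
10 for m=12, i=j=1).  That formula differs from standard Holm indexing and is
kept only so the worked-example arithmetic can be checked; the pipeline always
uses ``holm_correct``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import EdgeInference, symmetrize_and_rule

__all__ = [
    "holm_correct",
    "edge_test_count",
    "printed_correction_factor",
    "build_ci",
    "edge_table",
    "pair_table",
]


def holm_correct(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, in the original order."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    if np.any((pvalues < 0) | (pvalues > 1) | ~np.isfinite(pvalues)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="holm")[1]


def edge_test_count(p: int) -> int:
    """Number of ordered edge tests in a p-node network: m = p(p-1)."""
    if p < 2:
        raise ValueError("need p >= 2")
    return p * (p - 1)


def printed_correction_factor(m: int, i: int, j: int) -> int:
    """The worked example's correction factor ``m - i - j`` (see module docs)."""
    factor = m - i - j
    if factor <= 0:
        warnings.warn(
            f"correction factor m - i - j = {factor} is not positive; returning 0",
            stacklevel=2,
        )
        return 0
    return factor


def build_ci(estimate: float, se: float, alpha: float) -> tuple[float, float]:
    """Two-sided Gaussian confidence interval ``estimate +- z_{1-alpha/2} * se``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(estimate - z * se), float(estimate + z * se)


_COLUMNS = [
    "i", "j", "name_i", "name_j", "estimate", "se",
    "p_raw", "p_corrected", "ci_lower", "ci_upper", "significant",
]


def edge_table(
    entries: list[dict],
    names,
    alpha: float,
    correct: str | None = "holm",
    simultaneous: bool = False,
) -> pd.DataFrame:
    """Assemble ordered edge rows into the package's standard inference table.

    ``entries`` are dicts with keys i, j, estimate, se, p_raw and optionally
    p_corrected (methods that embed their own correction pass
    ``correct=None``).  CIs are built at level alpha (``alpha/m`` per interval
    when ``simultaneous``); significance is ``p_corrected <= alpha``.
    """
    df = pd.DataFrame(entries)
    if correct == "holm":
        df["p_corrected"] = holm_correct(df["p_raw"].to_numpy())
    elif correct is None:
        if "p_corrected" not in df:
            raise ValueError("entries must carry p_corrected when correct=None")
    else:
        raise ValueError(f"unknown correction {correct!r}")
    ci_alpha = alpha / len(df) if simultaneous else alpha
    z = stats.norm.ppf(1.0 - ci_alpha / 2.0)
    if simultaneous or "ci_lower" not in df:
        df["ci_lower"] = df["estimate"] - z * df["se"]
        df["ci_upper"] = df["estimate"] + z * df["se"]
    df["significant"] = df["p_corrected"] <= alpha
    df["name_i"] = [names[k] for k in df["i"]]
    df["name_j"] = [names[k] for k in df["j"]]
    return df[_COLUMNS].sort_values(["i", "j"], ignore_index=True)


def pair_table(edges: pd.DataFrame, alpha: float, rule: str = "and") -> pd.DataFrame:
    """Collapse the ordered edge table to unordered pair decisions.

    Applies the and-rule (or or-rule) via :func:`ggminfer.core.symmetrize_and_rule`
    and reports both the coefficient-scale and partial-correlation-scale
    combined estimates.
    """
    by_pair: dict[tuple[int, int], dict[int, pd.Series]] = {}
    for _, row in edges.iterrows():
        key = (min(row["i"], row["j"]), max(row["i"], row["j"]))
        by_pair.setdefault(key, {})[row["i"]] = row
    rows = []
    for (i, j), pair in sorted(by_pair.items()):
        if len(pair) != 2:
            raise ValueError(f"pair ({i}, {j}) lacks one of its two ordered results")
        res = {
            k: EdgeInference(
                i=int(r["i"]), j=int(r["j"]), estimate=float(r["estimate"]),
                se=float(r["se"]), p_raw=float(r["p_raw"]),
                p_corrected=float(r["p_corrected"]), ci_lower=float(r["ci_lower"]),
                ci_upper=float(r["ci_upper"]), significant=bool(r["significant"]),
            )
            for k, r in pair.items()
        }
        combined = symmetrize_and_rule(res[i], res[j], alpha, rule=rule)
        combined["name_i"] = pair[i]["name_i"]
        combined["name_j"] = pair[i]["name_j"]
        rows.append(combined)
    return pd.DataFrame(
        rows, columns=["i", "j", "name_i", "name_j", "estimate", "estimate_rho", "significant"]
    )
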