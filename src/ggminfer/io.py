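"""CSV/TSV input and output.

Data come in as a CSV with one header row (variable names) and a numeric
body; results go out as a TSV edge table plus a CSV adjacency matrix, and
simulation truths as an edge-list TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import DataMatrix, PrecisionModel

__all__ = ["read_data", "write_data", "write_truth", "save_results"]


def read_data(path) -> DataMatrix:
    """Read and validate an observations x variables CSV with a header row."""
    path = Path(path)
    df = pd.read_csv(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path.name}: non-numeric value {df.iat[r, c]!r} at row {r + 1}, "
            f"column {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path.name}: missing value at row {r + 1}, column {df.columns[c]!r}"
        )
    return DataMatrix.from_dataframe(numeric)


def write_data(data: DataMatrix, path) -> None:
    data.to_dataframe().to_csv(path, index=False)


def write_truth(model: PrecisionModel, path, names=None) -> None:
    """Write the true edge list as TSV: i, j, theta_ij, rho_ij."""
    model.to_edgelist(names).to_csv(path, sep="\t", index=False)


def save_results(results, directory) -> None:
    """Persist a fit: edge table (TSV), pair decisions (TSV), adjacency (CSV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if results.edge_table is not None:
        results.edge_table.to_csv(directory / "edges.tsv", sep="\t", index=False)
    results.pairs.to_csv(directory / "pairs.tsv", sep="\t", index=False)
    results.adjacency.to_csv(directory / "adjacency.csv")
    samples = results.extras.get("samples") if hasattr(results, "extras") else None
    if samples is not None:
        # per-edge bootstrap draws (one column per ordered edge, K rows)
        samples.to_csv(directory / "bootstrap_samples.tsv", sep="\t", index=False)
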