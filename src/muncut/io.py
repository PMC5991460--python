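"""Delimited-text input/output for layer matrices and clustering results.

The interchange format is plain delimited text (comma or tab, detected
from the header line): first row variable names, one subsequent row per
subject, fully numeric, no missing values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import Partition


class LayerParseError(ValueError):
    """Raised when a layer matrix file is malformed; names the location."""


def _detect_sep(path: Path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    if not header.strip():
        raise LayerParseError(f"{path}: empty file or blank header")
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_layer_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read one subjects-by-variables matrix with a variable-name header.

    Returns ``(matrix, names)``.  Ragged rows, non-numeric cells and
    missing values raise :class:`LayerParseError` naming the offending
    row and column.
    """
    path = Path(path)
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, header=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise LayerParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise LayerParseError(f"{path}: no data rows or columns")
    names = [str(c) for c in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise LayerParseError(
            f"{path}: non-numeric or missing value at subject row {r + 1}, "
            f"column '{names[c]}'"
        )
    return numeric.to_numpy(dtype=float), names


def write_layer_matrix(path: str | Path, M: np.ndarray, names: list[str]) -> None:
    """Write a matrix with a header row at full float precision."""
    pd.DataFrame(np.asarray(M), columns=list(names)).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_partition(path: str | Path, partition: Partition, names: list[str]) -> None:
    """Write (variable, layer, cluster) with 1-based cluster ids."""
    pd.DataFrame(
        {
            "variable": list(names),
            "layer": partition.layer_of,
            "cluster": partition.labels + 1,
        }
    ).to_csv(path, index=False)


def read_partition(path: str | Path) -> tuple[Partition, list[str]]:
    """Read a (variable, layer, cluster) table written by write_partition."""
    df = pd.read_csv(path)
    labels = df["cluster"].to_numpy(dtype=np.int64) - 1
    part = Partition(labels, df["layer"].to_numpy(dtype="<U1"), int(labels.max()) + 1)
    return part, df["variable"].astype(str).tolist()


def write_trace(path: str | Path, trace: np.ndarray, accepted: np.ndarray) -> None:
    """Write the annealing trace (iteration, objective, accepted)."""
    pd.DataFrame(
        {
            "iteration": np.arange(1, trace.size + 1),
            "objective": trace,
            "accepted": accepted.astype(int),
        }
    ).to_csv(path, index=False)
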