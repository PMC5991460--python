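"""Containers for aligned multilayer omics data and variable partitions.

The three layers are measured on the same ``n`` subjects: copy-number
variations ``X`` (n x r), gene expressions ``Y`` (n x p) and proteins
``Z`` (n x q).  Whenever the ``m = q + p + r`` variables of all layers are
handled as one "mega" vector, the fixed block order is (proteins, gene
expressions, CNVs), i.e. Z-block first, X-block last.  All partitions,
weight matrices and adjacency matrices in this package use that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: single-character layer tags in mega-vector order: P = protein,
#: G = gene expression, C = CNV.
LAYERS: tuple[str, str, str] = ("P", "G", "C")

_LAYER_INDEX = {tag: i for i, tag in enumerate(LAYERS)}


def _default_names(prefix: str, count: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(count)]


def _as_matrix(M, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError(f"{name} must be a 2-D subjects-by-variables matrix")
    if not np.isfinite(M).all():
        raise ValueError(f"{name} contains missing or non-finite entries")
    return M


@dataclass
class MultiLayerData:
    """Aligned (X, Y, Z) matrices with one row per subject.

    Parameters
    ----------
    X : ndarray, shape (n, r)
        CNV measurements.
    Y : ndarray, shape (n, p)
        Gene-expression measurements.
    Z : ndarray, shape (n, q)
        Protein measurements.
    x_names, y_names, z_names : list of str, optional
        Variable names per layer; generated when omitted.
    """

    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    x_names: list[str] = field(default_factory=list)
    y_names: list[str] = field(default_factory=list)
    z_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = _as_matrix(self.X, "X")
        self.Y = _as_matrix(self.Y, "Y")
        self.Z = _as_matrix(self.Z, "Z")
        n = self.X.shape[0]
        if self.Y.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("X, Y and Z must have the same number of rows (subjects)")
        if min(self.r, self.p, self.q) < 1:
            raise ValueError("each layer needs at least one variable")
        if not self.x_names:
            self.x_names = _default_names("cnv", self.r)
        if not self.y_names:
            self.y_names = _default_names("ge", self.p)
        if not self.z_names:
            self.z_names = _default_names("prot", self.q)
        for names, d, label in (
            (self.x_names, self.r, "X"),
            (self.y_names, self.p, "Y"),
            (self.z_names, self.q, "Z"),
        ):
            if len(names) != d:
                raise ValueError(f"{label} has {d} columns but {len(names)} names")

    # -- dimensions ---------------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def r(self) -> int:
        return self.X.shape[1]

    @property
    def p(self) -> int:
        return self.Y.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def m(self) -> int:
        return self.q + self.p + self.r

    # -- mega-vector views --------------------------------------------------
    def layer_of(self) -> np.ndarray:
        """Layer tag ('P'/'G'/'C') of each variable in mega order."""
        return np.array(
            ["P"] * self.q + ["G"] * self.p + ["C"] * self.r, dtype="<U1"
        )

    def var_names(self) -> list[str]:
        """All variable names in mega order (Z-block, Y-block, X-block)."""
        return list(self.z_names) + list(self.y_names) + list(self.x_names)

    def mega_matrix(self) -> np.ndarray:
        """Column-concatenated n x m matrix in mega order."""
        return np.hstack([self.Z, self.Y, self.X])

    def subset_subjects(self, idx: np.ndarray) -> "MultiLayerData":
        """Restrict to a subset of subjects (rows)."""
        idx = np.asarray(idx)
        return MultiLayerData(
            X=self.X[idx],
            Y=self.Y[idx],
            Z=self.Z[idx],
            x_names=list(self.x_names),
            y_names=list(self.y_names),
            z_names=list(self.z_names),
        )


@dataclass
class Partition:
    """Cluster assignment over all m variables of a multilayer dataset.

    ``labels`` are 0-based internally (clusters ``0 .. K-1``); file output
    uses 1-based cluster ids.  ``layer_of`` carries the 'P'/'G'/'C' tag of
    each variable so per-layer restrictions can be derived.
    """

    labels: np.ndarray
    layer_of: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.layer_of = np.asarray(self.layer_of, dtype="<U1")
        if self.labels.shape != self.layer_of.shape:
            raise ValueError("labels and layer_of must have the same length")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.K):
            raise ValueError("labels must lie in {0, ..., K-1}")
        bad = set(np.unique(self.layer_of)) - set(LAYERS)
        if bad:
            raise ValueError(f"unknown layer tags: {sorted(bad)}")

    @property
    def m(self) -> int:
        return self.labels.size

    def layer_mask(self, layer: str) -> np.ndarray:
        if layer not in _LAYER_INDEX:
            raise ValueError(f"layer must be one of {LAYERS}")
        return self.layer_of == layer

    def layer_labels(self, layer: str) -> np.ndarray:
        """Labels restricted to one layer's variables (mega order preserved)."""
        return self.labels[self.layer_mask(layer)]

    def sizes(self) -> np.ndarray:
        """Cluster sizes as a length-K vector."""
        return np.bincount(self.labels, minlength=self.K)

    def copy(self) -> "Partition":
        return Partition(self.labels.copy(), self.layer_of.copy(), self.K)
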