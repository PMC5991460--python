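"""Accuracy, stability and concordance measures on co-clustering matrices.

Every clustering of the m variables induces a binary adjacency
(co-clustering) matrix A with a_jl = 1 when variables j and l share a
cluster (diagonal all ones).  All evaluation statistics are functions of
these matrices, hence invariant to cluster relabeling:

* accuracy -- proportion of disagreeing entries between the true and the
  estimated adjacency matrices (0 = perfect recovery);
* stability -- entrywise co-clustering frequency across re-clusterings of
  random half-samples of subjects;
* concordance M(B|A) -- fraction of A's co-clustered pairs that B also
  co-clusters (asymmetric).

A distance-correlation screen is provided as a preprocessing utility for
real-data analyses, ranking candidate variables by the strength of their
(possibly nonlinear) dependence on an anchor layer.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import MultiLayerData, Partition


def adjacency(partition: Partition) -> np.ndarray:
    """Binary m x m co-clustering matrix of a partition (diagonal 1)."""
    lab = partition.labels
    return (lab[:, None] == lab[None, :]).astype(np.uint8)


def accuracy(A_true: np.ndarray, A_hat: np.ndarray, form: str = "disagreement") -> float:
    """Clustering error between two adjacency matrices.

    ``form="disagreement"`` (default) is the proportion of entries on
    which the matrices differ, sum|A_T - A_hat| / m^2; it is 0 exactly
    when the partitions coincide up to relabeling and is symmetric in its
    arguments.  ``form="overlap_complement"`` is 1 - sum(A_T * A_hat)/m^2,
    retained for audit; it cannot reach 0 even at perfect recovery.
    """
    A_true = np.asarray(A_true)
    A_hat = np.asarray(A_hat)
    if A_true.shape != A_hat.shape or A_true.ndim != 2:
        raise ValueError("adjacency matrices must share a square shape")
    m2 = A_true.size
    if form == "disagreement":
        return float(np.abs(A_true.astype(np.int8) - A_hat.astype(np.int8)).sum() / m2)
    if form == "overlap_complement":
        return float(1.0 - (A_true.astype(np.int64) * A_hat).sum() / m2)
    raise ValueError("form must be 'disagreement' or 'overlap_complement'")


def concordance(A_hat: np.ndarray, B_hat: np.ndarray) -> float:
    """M(B|A): fraction of A's co-clustered pairs also co-clustered by B.

    Diagonal entries participate in both sums, so the value lies in
    (0, 1] and equals 1 when B co-clusters everything A does.
    """
    A_hat = np.asarray(A_hat, dtype=np.int64)
    B_hat = np.asarray(B_hat, dtype=np.int64)
    if A_hat.shape != B_hat.shape:
        raise ValueError("adjacency matrices must share a shape")
    denom = A_hat.sum()
    if denom == 0:
        raise ValueError("reference adjacency has no co-clustered pairs")
    return float((A_hat * B_hat).sum() / denom)


def stability(
    data: MultiLayerData,
    clusterer: Callable[[MultiLayerData], Partition],
    N: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Mean adjacency over N re-clusterings of random half-samples.

    Each round selects n/2 subjects without replacement, re-runs
    ``clusterer`` and accumulates the resulting adjacency matrix; entries
    are co-clustering frequencies in [0, 1] with unit diagonal.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    half = data.n // 2
    acc = np.zeros((data.m, data.m))
    for _ in range(N):
        idx = rng.choice(data.n, size=half, replace=False)
        acc += adjacency(clusterer(data.subset_subjects(idx)))
    return acc / N


def distance_correlation(x: np.ndarray, Y: np.ndarray) -> float:
    """Sample distance correlation between a vector and a matrix.

    Classic (biased) V-statistic: Euclidean distance matrices of ``x``
    (n,) and ``Y`` (n, k) are double-centered and correlated.  Returns a
    value in [0, 1]; 0 iff empirical distance covariance vanishes.
    """
    x = np.asarray(x, float).reshape(-1, 1)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if x.shape[0] != Y.shape[0]:
        raise ValueError("x and Y must have the same number of rows")

    def centered(M: np.ndarray) -> np.ndarray:
        D = squareform(pdist(M))
        return D - D.mean(axis=0) - D.mean(axis=1)[:, None] + D.mean()

    A = centered(x)
    B = centered(Y)
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


def dcor_screen(candidates: np.ndarray, anchors: np.ndarray, top_k: int) -> np.ndarray:
    """Indices of the top_k candidate columns by distance correlation.

    Each candidate column is scored against the full anchor matrix; ties
    are broken toward the smaller index.
    """
    candidates = np.asarray(candidates, float)
    anchors = np.asarray(anchors, float)
    if not 1 <= top_k <= candidates.shape[1]:
        raise ValueError("top_k must be in 1..n_candidates")
    scores = np.array(
        [distance_correlation(candidates[:, j], anchors) for j in range(candidates.shape[1])]
    )
    order = np.argsort(-scores, kind="stable")
    return order[:top_k]


def plot_stability(M: np.ndarray, path: str, labels: np.ndarray | None = None) -> None:
    """Render a stability matrix as a heatmap (warm = high frequency)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(M, cmap="coolwarm", vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.set_xlabel("variable")
    ax.set_ylabel("variable")
    fig.colorbar(im, ax=ax, label="co-clustering frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
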