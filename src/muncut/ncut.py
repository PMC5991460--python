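"""Normalized-cut measures for within-layer and multilayer partitions.

For a weight matrix W and a partition A_1, ..., A_K of its index set the
NCut measure is

    NCut = sum_k cut(A_k) / cutvol(A_k),

with cut(A_k) the total weight between A_k and its complement and
cutvol(A_k) the total weight of ordered pairs inside A_k.  The multilayer
objective combines the cross-layer NCut (on the block weight matrix W~,
whose within-layer blocks are zero) with the within-layer NCut of each
layer:

    MuNCut(A) = NCut_multi(A; W~) + gamma * [NCut_C + NCut_G + NCut_P].

Degenerate clusters are handled explicitly: a cluster with zero internal
volume and zero cut contributes 0 (empty clusters, isolated singletons),
while zero volume with positive cut contributes cut / epsilon_vol -- a
large but finite penalty that keeps the annealer's objective well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Partition, LAYERS
from .weights import WeightSet

#: volume guard for clusters with positive cut but zero internal weight
EPSILON_VOL = 1e-8


@dataclass
class MuNCutConfig:
    """Knobs of the clustering objective.

    gamma : weight of the within-layer NCut term (>= 0).
    sigma : kernel bandwidth used when building weights.
    epsilon_vol : volume guard for degenerate clusters.
    diag_in_cutvol : include self-weights w_jj in cluster volume.
    """

    gamma: float = 0.5
    sigma: float = 1.0
    epsilon_vol: float = EPSILON_VOL
    diag_in_cutvol: bool = True

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.epsilon_vol <= 0:
            raise ValueError("epsilon_vol must be positive")


def _cluster_mask(labels: np.ndarray, k: int, K: int) -> np.ndarray:
    if not 0 <= k < K:
        raise ValueError(f"cluster index {k} outside 0..{K - 1}")
    return labels == k


def cut(labels: np.ndarray, W: np.ndarray, k: int, K: int | None = None) -> float:
    """Total weight between cluster k and all other variables."""
    labels = np.asarray(labels)
    K = int(labels.max()) + 1 if K is None else K
    mask = _cluster_mask(labels, k, K)
    if not mask.any() or mask.all():
        return 0.0
    return float(W[np.ix_(mask, ~mask)].sum())


def cutvol(
    labels: np.ndarray,
    W: np.ndarray,
    k: int,
    K: int | None = None,
    include_diag: bool = True,
) -> float:
    """Total weight over ordered pairs inside cluster k."""
    labels = np.asarray(labels)
    K = int(labels.max()) + 1 if K is None else K
    mask = _cluster_mask(labels, k, K)
    if not mask.any():
        return 0.0
    block = W[np.ix_(mask, mask)].copy()
    if not include_diag:
        # zero the diagonal before summing: subtracting the trace afterwards
        # would swallow off-diagonal weights many orders smaller than w_jj
        np.fill_diagonal(block, 0.0)
    return float(block.sum())


def _safe_ratio(c: float, v: float, eps: float) -> float:
    if v > 0:
        return c / v
    if c > 0:
        return c / eps
    return 0.0


def ncut_measure(
    labels: np.ndarray,
    W: np.ndarray,
    K: int | None = None,
    epsilon_vol: float = EPSILON_VOL,
    include_diag: bool = True,
) -> float:
    """NCut of a partition over a single weight matrix."""
    labels = np.asarray(labels)
    K = int(labels.max()) + 1 if K is None else K
    total = 0.0
    for k in range(K):
        c = cut(labels, W, k, K)
        v = cutvol(labels, W, k, K, include_diag)
        total += _safe_ratio(c, v, epsilon_vol)
    return total


def ncut_single(
    partition: Partition,
    weights: WeightSet,
    epsilon_vol: float = EPSILON_VOL,
    include_diag: bool = True,
) -> float:
    """Sum of the three within-layer NCut measures NCut_C + NCut_G + NCut_P.

    Each layer's measure uses the partition restricted to that layer's
    variables and that layer's weight matrix.
    """
    per_layer = {"C": weights.W_C, "G": weights.W_G, "P": weights.W_P}
    total = 0.0
    for layer in LAYERS:
        lab = partition.layer_labels(layer)
        total += ncut_measure(lab, per_layer[layer], partition.K, epsilon_vol, include_diag)
    return total


def ncut_multi(
    partition: Partition,
    W_mega: np.ndarray,
    epsilon_vol: float = EPSILON_VOL,
) -> float:
    """NCut of the full m-variable partition on the cross-layer matrix.

    Because the within-layer blocks of W~ are zero, cluster volume here
    counts only cross-layer within-cluster pairs; a cluster drawn from a
    single layer has zero volume and is penalized through the guard.
    """
    if W_mega.shape[0] != partition.m:
        raise ValueError("W_mega does not match the partition size")
    return ncut_measure(partition.labels, W_mega, partition.K, epsilon_vol, False)


def muncut_objective(
    partition: Partition,
    weights: WeightSet,
    gamma: float = 0.5,
    epsilon_vol: float = EPSILON_VOL,
    include_diag: bool = True,
) -> float:
    """The multilayer clustering objective NCut_multi + gamma * NCut_single."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    value = ncut_multi(partition, weights.W_mega, epsilon_vol)
    if gamma > 0:
        value += gamma * ncut_single(partition, weights, epsilon_vol, include_diag)
    return value
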