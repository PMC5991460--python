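"""Comparator clusterings: pooled, layer-matched, and community detection.

Pooled methods (KM, SC, HC) treat every variable of the concatenated
(Z, Y, X) matrix as a point in subject space and cluster all m points at
once, ignoring layer identity.  Matched methods (KM*, SC*, HC*) cluster
each layer separately into the same number of clusters and then align
clusters across layers -- gene-expression clusters to CNV clusters and
protein clusters to gene-expression clusters -- by maximizing the total
cross-layer association, producing one merged partition.

Community-detection baselines (Louvain, fast greedy) are thin adapters
over python-igraph, run on the same combined similarity matrix the main
method uses (cross-layer blocks plus gamma-weighted within-layer blocks).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering

from .data import MultiLayerData, Partition
from .weights import (
    DEFAULT_SCALE_BY_N,
    WeightSet,
    standardize_columns,
    within_layer_weights,
)

_METHODS = ("KM", "SC", "HC")

#: above this K the K! correspondence search falls back to an optimal
#: assignment on the association matrix
EXHAUSTIVE_MATCH_LIMIT = 6


def _cluster_points(
    points: np.ndarray,
    method: str,
    K: int,
    seed: int,
    sigma: float = 1.0,
    scale_by_n: bool = DEFAULT_SCALE_BY_N,
) -> np.ndarray:
    """Cluster rows of ``points`` (variables in subject space) into K groups."""
    if method == "KM":
        km = KMeans(n_clusters=K, random_state=seed, n_init=10)
        return km.fit_predict(points)
    if method == "SC":
        W = within_layer_weights(points.T, sigma=sigma, scale_by_n=scale_by_n)
        sc = SpectralClustering(
            n_clusters=K,
            affinity="precomputed",
            random_state=seed,
            assign_labels="kmeans",
        )
        return sc.fit_predict(W)
    if method == "HC":
        hc = AgglomerativeClustering(n_clusters=K, linkage="average", metric="euclidean")
        return hc.fit_predict(points)
    raise ValueError(f"method must be one of {_METHODS}")


def pooled_clustering(
    data: MultiLayerData,
    method: str,
    K: int,
    seed: int = 0,
    sigma: float = 1.0,
    scale_by_n: bool = DEFAULT_SCALE_BY_N,
    standardize: bool = False,
) -> Partition:
    """Cluster all m variables jointly as points in subject space.

    By default the pooled matrix is used as-is: the layers keep their
    native scales, exactly as when a single-type clustering method is
    applied directly to concatenated multi-omics data.  This is what
    makes pooled baselines split clusters by data type -- the behaviour
    these comparators are meant to exhibit.  Set ``standardize=True`` to
    put all variables on a common scale first.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > data.m:
        raise ValueError("K cannot exceed the number of variables")
    pooled = data.mega_matrix()
    if standardize:
        pooled = standardize_columns(pooled)
    labels = _cluster_points(pooled.T, method, K, seed, sigma, scale_by_n)
    return Partition(labels, data.layer_of(), K)


def cluster_association(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    data_a: np.ndarray,
    data_b: np.ndarray,
    K: int,
) -> np.ndarray:
    """K x K matrix of mean |Pearson correlation| between cluster pairs.

    Entry (k, k') averages |cor| over all (variable in cluster k of layer
    A, variable in cluster k' of layer B) pairs.
    """
    A = standardize_columns(data_a)
    B = standardize_columns(data_b)
    n = A.shape[0]
    C = np.abs(A.T @ B) / n  # |corr| between all cross-layer column pairs
    out = np.zeros((K, K))
    for k in range(K):
        ka = labels_a == k
        for kk in range(K):
            kb = labels_b == kk
            if ka.any() and kb.any():
                out[k, kk] = C[np.ix_(ka, kb)].mean()
    return out


def best_correspondence(assoc: np.ndarray) -> tuple[np.ndarray, float]:
    """Bijection of columns onto rows maximizing the total association.

    Returns ``(col_for_row, total)`` where ``col_for_row[k]`` is the
    column cluster matched to row cluster k.  Exhaustive over the K!
    permutations for K <= EXHAUSTIVE_MATCH_LIMIT, otherwise solved as an
    optimal assignment problem.
    """
    K = assoc.shape[0]
    if assoc.shape != (K, K):
        raise ValueError("association matrix must be square")
    if K <= EXHAUSTIVE_MATCH_LIMIT:
        best_perm, best_total = None, -np.inf
        for perm in permutations(range(K)):
            total = sum(assoc[k, perm[k]] for k in range(K))
            if total > best_total:
                best_total, best_perm = total, perm
        return np.array(best_perm), float(best_total)
    rows, cols = linear_sum_assignment(-assoc)
    return cols[np.argsort(rows)], float(assoc[rows, cols].sum())


@dataclass
class MatchedClustering:
    """Per-layer clusterings aligned across layers into one partition."""

    labels_P: np.ndarray
    labels_G: np.ndarray
    labels_C: np.ndarray
    cnv_for_ge: np.ndarray  # CNV cluster matched to each GE cluster
    prot_for_ge: np.ndarray  # protein cluster matched to each GE cluster
    merged: Partition


def layerwise_matched_clustering(
    data: MultiLayerData,
    method: str,
    K: int,
    seed: int = 0,
    sigma: float = 1.0,
    scale_by_n: bool = DEFAULT_SCALE_BY_N,
) -> MatchedClustering:
    """Cluster each layer separately, then align clusters across layers.

    Gene-expression cluster ids anchor the merged labels; each CNV and
    protein cluster inherits the id of the gene-expression cluster it is
    matched to.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    Xs = standardize_columns(data.X)
    Ys = standardize_columns(data.Y)
    Zs = standardize_columns(data.Z)
    lab_C = _cluster_points(Xs.T, method, K, seed, sigma, scale_by_n)
    lab_G = _cluster_points(Ys.T, method, K, seed + 1, sigma, scale_by_n)
    lab_P = _cluster_points(Zs.T, method, K, seed + 2, sigma, scale_by_n)

    assoc_gc = cluster_association(lab_G, lab_C, data.Y, data.X, K)
    cnv_for_ge, _ = best_correspondence(assoc_gc)
    assoc_gp = cluster_association(lab_G, lab_P, data.Y, data.Z, K)
    prot_for_ge, _ = best_correspondence(assoc_gp)

    # invert: cluster id in the foreign layer -> anchoring GE cluster id
    ge_for_cnv = np.empty(K, dtype=np.int64)
    ge_for_cnv[cnv_for_ge] = np.arange(K)
    ge_for_prot = np.empty(K, dtype=np.int64)
    ge_for_prot[prot_for_ge] = np.arange(K)

    merged_labels = np.concatenate(
        [ge_for_prot[lab_P], lab_G, ge_for_cnv[lab_C]]
    )
    merged = Partition(merged_labels, data.layer_of(), K)
    return MatchedClustering(
        labels_P=lab_P,
        labels_G=lab_G,
        labels_C=lab_C,
        cnv_for_ge=cnv_for_ge,
        prot_for_ge=prot_for_ge,
        merged=merged,
    )


def combined_similarity(weights: WeightSet, gamma: float) -> np.ndarray:
    """Cross-layer matrix plus gamma-weighted within-layer blocks.

    The same similarity input the multilayer objective sees, collapsed to
    a single symmetric matrix (zero diagonal) for graph-based methods.
    """
    W = weights.W_mega + gamma * weights.within_blockdiag()
    np.fill_diagonal(W, 0.0)
    return W


def community_baselines(
    W: np.ndarray,
    layer_of: np.ndarray,
    method: str,
    seed: int | None = None,
) -> Partition:
    """Louvain ("LC") or fast-greedy ("FGC") community detection on W.

    Thin adapter over python-igraph; the number of communities is chosen
    by the algorithm.  Raises ImportError with guidance if igraph is not
    installed.
    """
    try:
        import igraph
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "community baselines require python-igraph; install the "
            "'community' extra (pip install muncut[community])"
        ) from exc
    W = np.asarray(W, float)
    m = W.shape[0]
    if seed is not None:
        import random

        igraph.set_random_number_generator(random.Random(seed))
    iu, ju = np.triu_indices(m, k=1)
    keep = W[iu, ju] > 0
    edges = list(zip(iu[keep].tolist(), ju[keep].tolist()))
    g = igraph.Graph(n=m, edges=edges)
    wts = W[iu, ju][keep].tolist()
    if method == "LC":
        clustering = g.community_multilevel(weights=wts)
    elif method == "FGC":
        clustering = g.community_fastgreedy(weights=wts).as_clustering()
    else:
        raise ValueError("method must be 'LC' or 'FGC'")
    labels = np.asarray(clustering.membership, dtype=np.int64)
    return Partition(labels, np.asarray(layer_of, dtype="<U1"), int(labels.max()) + 1)
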