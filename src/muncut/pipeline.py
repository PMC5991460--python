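"""End-to-end multilayer NCut clustering: regressions, weights, annealing."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .anneal import SAConfig, SAState, run_sa
from .data import MultiLayerData, Partition
from .regnet import RegulationFit, predicted_layers
from .weights import (
    DEFAULT_NULL_COR,
    DEFAULT_SCALE_BY_N,
    DEFAULT_SIGMA,
    WeightSet,
    build_weights,
)

logger = logging.getLogger("muncut")


def spectral_init(
    weights: WeightSet, K: int, gamma: float, seed: int = 0
) -> np.ndarray:
    """Spectral-embedding starting labels for the annealer.

    Clusters the combined similarity matrix (cross-layer blocks plus
    gamma-weighted within-layer blocks) with a normalized-Laplacian
    spectral embedding and k-means; the annealer then refines this
    partition under the exact objective.
    """
    from sklearn.cluster import SpectralClustering

    from .baselines import combined_similarity

    W = combined_similarity(weights, gamma)
    # small uniform lift keeps the graph connected when many variables
    # have vanishing similarity to everything
    W = W + 1e-10
    sc = SpectralClustering(
        n_clusters=K, affinity="precomputed", random_state=seed,
        assign_labels="kmeans",
    )
    return sc.fit_predict(W)


@dataclass
class MuNCutResult:
    """Everything produced by one clustering run."""

    partition: Partition
    objective: float
    state: SAState
    weights: WeightSet
    fit: RegulationFit
    gamma: float
    K: int


def fit_muncut(
    data: MultiLayerData,
    K: int = 2,
    B: int = 3000,
    L: float = 1000.0,
    gamma: float = 0.5,
    dist: str = "gaussian",
    sigma: float = DEFAULT_SIGMA,
    seed: int = 0,
    schedule: str = "inverse_log",
    scale_by_n: bool = DEFAULT_SCALE_BY_N,
    null_cor: float = DEFAULT_NULL_COR,
    alpha: float = 0.5,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    rule: str = "1se",
    init: str = "spectral",
    diag_in_cutvol: bool = True,
    weights: WeightSet | None = None,
    fit: RegulationFit | None = None,
    keep_trace: bool = True,
) -> MuNCutResult:
    """Cluster the variables of a multilayer dataset.

    Steps: column standardization; elastic-net regressions CNV -> GE and
    GE -> protein; Gaussian-kernel weight matrices (within layers on the
    observed data, across layers on the predicted layers); simulated
    annealing on the combined objective, started from a spectral
    embedding of the combined similarity (``init="spectral"``, default)
    or from uniform random labels (``init="random"``).  Precomputed
    ``weights`` (and the ``fit`` they came from) can be passed to
    re-anneal at a different (gamma, K) without refitting.

    Returns a :class:`MuNCutResult`; ``result.partition`` is the best
    partition found.
    """
    if dist != "gaussian":
        raise ValueError("only the Gaussian kernel distance is supported")
    if init not in ("spectral", "random"):
        raise ValueError("init must be 'spectral' or 'random'")
    logger.info(
        "muncut: K=%d B=%d L=%g gamma=%g sigma=%g schedule=%s scale_by_n=%s "
        "init=%s lambda_rule=%s (cutvol includes the diagonal: %s; "
        "accuracy form: disagreement)",
        K, B, L, gamma, sigma, schedule, scale_by_n, init, rule, diag_in_cutvol,
    )
    if weights is None:
        if fit is None:
            fit = predicted_layers(data, alpha=alpha, lambda_grid=lambda_grid,
                                   cv_folds=cv_folds, seed=seed, rule=rule)
        weights = build_weights(data, fit.Y_hat, fit.Z_hat, sigma, scale_by_n,
                                null_cor)
    init_labels = (
        spectral_init(weights, K, gamma, seed) if init == "spectral" else None
    )
    config = SAConfig(K=K, B=B, L=L, seed=seed, schedule=schedule,
                      diag_in_cutvol=diag_in_cutvol)
    state = run_sa(weights, data.layer_of(), config, gamma,
                   init_labels=init_labels, keep_trace=keep_trace)
    return MuNCutResult(
        partition=state.best_partition,
        objective=state.best_objective,
        state=state,
        weights=weights,
        fit=fit,
        gamma=gamma,
        K=K,
    )


def muncut(
    Z: np.ndarray,
    Y: np.ndarray,
    X: np.ndarray,
    K: int = 2,
    B: int = 3000,
    L: float = 1000.0,
    gamma: float = 0.5,
    dist: str = "gaussian",
    sigma: float = DEFAULT_SIGMA,
    **kwargs,
) -> MuNCutResult:
    """Array-level convenience wrapper over :func:`fit_muncut`.

    ``Z`` is the protein matrix, ``Y`` gene expressions and ``X`` CNVs,
    all subjects-by-variables.
    """
    data = MultiLayerData(X=np.asarray(X), Y=np.asarray(Y), Z=np.asarray(Z))
    return fit_muncut(data, K=K, B=B, L=L, gamma=gamma, dist=dist, sigma=sigma, **kwargs)
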