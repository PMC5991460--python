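"""Cross-validation selection of the (gamma, K) pair.

A candidate clustering is scored by how well it supports within-cluster
prediction: on held-out subjects, gene expressions are predicted from the
CNVs sharing their cluster and proteins from the gene expressions sharing
their cluster, both with elastic-net fits trained on the training
subjects.  Good clusterings group regulators with their targets and so
predict well; the (gamma, K) pair minimizing the total prediction error
over several random train/test splits is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MultiLayerData, Partition
from .regnet import fit_enet_layer, predicted_layers
from .weights import build_weights


@dataclass
class TuningGrid:
    """Search grid and splitting scheme for (gamma, K) selection."""

    gamma_values: list[float] = field(default_factory=lambda: [0.1, 0.5, 1.0])
    K_values: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    n_splits: int = 5
    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gamma_values or not self.K_values:
            raise ValueError("grids must be nonempty")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if any(K < 2 for K in self.K_values):
            raise ValueError("all K values must be >= 2")


def _standardize_pair(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize both sets with the training means and sds."""
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    tr = (train - mean) / safe
    te = (test - mean) / safe
    tr[:, sd == 0] = 0.0
    te[:, sd == 0] = 0.0
    return tr, te


def _within_cluster_sse(
    train_pred: np.ndarray,
    train_resp: np.ndarray,
    test_pred: np.ndarray,
    test_resp: np.ndarray,
    pred_labels: np.ndarray,
    resp_labels: np.ndarray,
    K: int,
    alpha: float,
    cv_folds: int,
    seed: int,
) -> float:
    """Summed squared test error of per-cluster regressions."""
    total = 0.0
    for k in range(K):
        resp_idx = np.flatnonzero(resp_labels == k)
        if resp_idx.size == 0:
            continue
        pred_idx = np.flatnonzero(pred_labels == k)
        if pred_idx.size == 0:
            # no predictors share the cluster: score the centered response
            total += float((test_resp[:, resp_idx] ** 2).sum())
            continue
        coefs = fit_enet_layer(
            train_pred[:, pred_idx],
            train_resp[:, resp_idx],
            alpha=alpha,
            cv_folds=cv_folds,
            seed=seed,
        )
        resid = test_resp[:, resp_idx] - test_pred[:, pred_idx] @ coefs
        total += float((resid**2).sum())
    return total


def cluster_prediction_error(
    train: MultiLayerData,
    test: MultiLayerData,
    partition: Partition,
    alpha: float = 0.5,
    cv_folds: int = 5,
    seed: int = 0,
) -> float:
    """Held-out within-cluster prediction error of a partition.

    All matrices are standardized with training-set statistics; the error
    is the summed squared test residual over every gene expression
    (predicted from same-cluster CNVs) and every protein (predicted from
    same-cluster gene expressions).
    """
    if test.n < 1:
        raise ValueError("test set is empty")
    if partition.m != train.m:
        raise ValueError("partition does not match the data dimensions")
    Xtr, Xte = _standardize_pair(train.X, test.X)
    Ytr, Yte = _standardize_pair(train.Y, test.Y)
    Ztr, Zte = _standardize_pair(train.Z, test.Z)
    lab_C = partition.layer_labels("C")
    lab_G = partition.layer_labels("G")
    lab_P = partition.layer_labels("P")
    err = _within_cluster_sse(
        Xtr, Ytr, Xte, Yte, lab_C, lab_G, partition.K, alpha, cv_folds, seed
    )
    err += _within_cluster_sse(
        Ytr, Ztr, Yte, Zte, lab_G, lab_P, partition.K, alpha, cv_folds, seed + 1
    )
    return err


def select_gamma_K(
    data: MultiLayerData,
    grid: TuningGrid,
    B: int = 3000,
    L: float = 1000.0,
    sigma: float = 1.0,
    schedule: str = "inverse_log",
    alpha: float = 0.5,
    cv_folds: int = 5,
    seed_sa: int = 0,
) -> tuple[float, int, pd.DataFrame]:
    """Pick the (gamma, K) pair with the smallest summed prediction error.

    For each random split, the regulatory regressions and weight matrices
    are computed once on the training subjects and the annealer is re-run
    per (gamma, K).  Ties break toward smaller K, then smaller gamma.

    Returns ``(gamma, K, error_table)`` with one table row per
    (gamma, K, split).
    """
    from .pipeline import fit_muncut  # local import to avoid a cycle

    rng = np.random.default_rng(grid.seed)
    rows = []
    for split in range(grid.n_splits):
        perm = rng.permutation(data.n)
        n_train = max(2, int(round(grid.train_fraction * data.n)))
        if n_train >= data.n:
            raise ValueError("train fraction leaves no test subjects")
        train = data.subset_subjects(perm[:n_train])
        test = data.subset_subjects(perm[n_train:])
        fit = predicted_layers(data=train, alpha=alpha, cv_folds=cv_folds,
                               seed=grid.seed + split)
        weights = build_weights(train, fit.Y_hat, fit.Z_hat, sigma)
        for K in grid.K_values:
            for gamma in grid.gamma_values:
                result = fit_muncut(
                    train, K=K, B=B, L=L, gamma=gamma, sigma=sigma,
                    seed=seed_sa + split, schedule=schedule,
                    weights=weights, fit=fit, keep_trace=False,
                )
                err = cluster_prediction_error(
                    train, test, result.partition, alpha, cv_folds, grid.seed + split
                )
                rows.append({"gamma": gamma, "K": K, "split": split, "error": err})
    table = pd.DataFrame(rows)
    totals = table.groupby(["gamma", "K"], as_index=False)["error"].sum()
    # ties break toward smaller K then smaller gamma
    totals = totals.sort_values(["error", "K", "gamma"], kind="stable")
    best = totals.iloc[0]
    return float(best["gamma"]), int(best["K"]), table
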