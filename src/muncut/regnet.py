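"""Elastic-net regressions describing cross-layer regulation.

Gene expressions are modelled as linear functions of CNVs and proteins as
linear functions of gene expressions,

    Y = X b1 + e1,    Z = Y b2 + e2,

and each coefficient column is estimated by the elastic net,

    argmin_b ||y - M b||_2^2 + lambda [ (1 - alpha) ||b||_2^2 + alpha ||b||_1 ].

Responses decouple under this penalty, so the multi-response fit is b
independent penalized regressions sharing a predictor matrix.  The fitted
values Yhat = X b1_hat and Zhat = Y b2_hat are the inputs to the
cross-layer similarity matrix.

Coordinate descent is scikit-learn's; this module maps the penalty above
onto scikit-learn's parametrization and adds per-response lambda
selection by k-fold cross-validation over a shared geometric grid,
computed efficiently with precomputed Gram matrices (covariance updates,
as in glmnet).  Pure ridge (alpha = 0) uses the closed form through one
eigendecomposition of the Gram matrix per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from .data import MultiLayerData
from .weights import standardize_columns


def _sklearn_penalty(lam: float, alpha: float, n: int) -> tuple[float, float]:
    """Map (lambda, alpha) of the objective above to sklearn's (alpha, l1_ratio).

    sklearn minimizes  ||y - Mb||^2 / (2n) + a * l1 * ||b||_1
                       + 0.5 * a * (1 - l1) * ||b||_2^2,
    so a = lambda (2 - alpha) / (2n) and l1 = alpha / (2 - alpha).
    """
    a = lam * (2.0 - alpha) / (2.0 * n)
    l1 = alpha / (2.0 - alpha)
    return a, l1


def default_lambda_grid(
    predictors: np.ndarray,
    responses: np.ndarray,
    alpha: float = 0.5,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 0.01,
) -> np.ndarray:
    """Descending geometric lambda grid from the smallest all-zero lambda.

    The upper end is the smallest lambda at which every coefficient of
    every response is zero (from the l1 part of the penalty; for pure
    ridge the alpha = 0.001 entry point stands in, mirroring common
    practice).  The default depth of 1/100 follows the usual convention
    for under-determined fits.
    """
    X = np.asarray(predictors, float)
    Y = np.asarray(responses, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    alpha_eff = max(alpha, 1e-3)
    gmax = np.abs(X.T @ Y).max()
    if gmax <= 0:
        return np.array([1.0])
    lam_max = 2.0 * gmax / alpha_eff
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, num=n_lambdas)


def _fit_at(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    alpha: float,
    model: ElasticNet | None = None,
    tol: float = 1e-4,
) -> ElasticNet:
    """One multi-response fit at a fixed penalty (warm-startable)."""
    a, l1 = _sklearn_penalty(lam, alpha, X.shape[0])
    if model is None:
        model = ElasticNet(
            alpha=a, l1_ratio=l1, fit_intercept=False,
            warm_start=True, tol=tol, max_iter=2000,
        )
    else:
        model.set_params(alpha=a, l1_ratio=l1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        model.fit(X, Y)
    return model


def _coef_matrix(model: ElasticNet, a: int, b: int) -> np.ndarray:
    coef = np.asarray(model.coef_)
    if coef.ndim == 1:
        coef = coef[None, :]
    return coef.T.reshape(a, b)


def _ridge_path(G_eig: tuple[np.ndarray, np.ndarray], XtY: np.ndarray,
                lams: np.ndarray) -> np.ndarray:
    """Exact ridge solutions for all penalties: (n_lam, a, b) array."""
    w, V = G_eig
    VtXtY = V.T @ XtY  # a x b
    return np.stack([V @ (VtXtY / (w + lam)[:, None]) for lam in lams])


def _cv_fit_ridge(X, Y, grid, cv_folds, seed):
    n, a = X.shape
    b = Y.shape[1]
    cv_err = np.zeros((grid.size, b))
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for train, val in kf.split(X):
        Xtr = X[train]
        eig = np.linalg.eigh(Xtr.T @ Xtr)
        paths = _ridge_path((eig[0], eig[1]), Xtr.T @ Y[train], grid)
        for gi in range(grid.size):
            resid = Y[val] - X[val] @ paths[gi]
            cv_err[gi] += (resid**2).sum(axis=0)
    best = cv_err.argmin(axis=0)
    eig = np.linalg.eigh(X.T @ X)
    paths = _ridge_path((eig[0], eig[1]), X.T @ Y, grid)
    coefs = np.empty((a, b))
    for j in range(b):
        coefs[:, j] = paths[best[j], :, j]
    return coefs


def _cv_fit_enet(X, Y, alpha, grid, cv_folds, seed, tol, rule="min"):
    n, a = X.shape
    b = Y.shape[1]
    l1 = alpha / (2.0 - alpha)
    Xf = np.asfortranarray(X)
    cv_sse = np.zeros((grid.size, b, cv_folds))
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for fold, (train, val) in enumerate(kf.split(X)):
            Xtr = np.asfortranarray(X[train])
            G = np.ascontiguousarray(Xtr.T @ Xtr)
            XtY = np.asfortranarray(Xtr.T @ Y[train])  # contiguous columns
            Xval = X[val]
            alphas_sk = grid * (2.0 - alpha) / (2.0 * Xtr.shape[0])
            for j in range(b):
                _, coefs, _ = enet_path(
                    Xtr, Y[train, j], l1_ratio=l1, alphas=alphas_sk,
                    precompute=G, Xy=XtY[:, j], check_input=False, tol=tol,
                )
                resid = Y[val, j][:, None] - Xval @ coefs
                cv_sse[:, j, fold] = (resid**2).mean(axis=0)
        cv_mean = cv_sse.mean(axis=2)
        best = cv_mean.argmin(axis=0)
        if rule == "1se":
            # largest lambda whose CV error is within one standard error of
            # the minimum (grid is descending, so the smallest index works)
            cv_se = cv_sse.std(axis=2, ddof=1) / np.sqrt(cv_folds)
            for j in range(b):
                limit = cv_mean[best[j], j] + cv_se[best[j], j]
                best[j] = int(np.argmax(cv_mean[:, j] <= limit))
        G = np.ascontiguousarray(Xf.T @ Xf)
        XtY = np.asfortranarray(Xf.T @ Y)
        alphas_sk = grid * (2.0 - alpha) / (2.0 * n)
        coefs_out = np.zeros((a, b))
        for j in range(b):
            _, coefs, _ = enet_path(
                Xf, Y[:, j], l1_ratio=l1, alphas=alphas_sk[: best[j] + 1],
                precompute=G, Xy=XtY[:, j], check_input=False, tol=tol,
            )
            coefs_out[:, j] = coefs[:, -1]
    return coefs_out


def fit_enet_layer(
    predictors: np.ndarray,
    responses: np.ndarray,
    alpha: float = 0.5,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    tol: float = 1e-4,
    rule: str = "min",
) -> np.ndarray:
    """Fit one elastic-net regression per response column.

    Parameters
    ----------
    predictors : ndarray, shape (n, a)
    responses : ndarray, shape (n, b) or (n,)
    alpha : float in [0, 1]
        Mix between ridge (0) and lasso (1) penalties.
    lambda_grid : array-like, optional
        Candidate penalties; a data-driven descending geometric grid is
        used when omitted.  A single-element grid skips cross-validation.
    cv_folds : int
        Folds for the per-response lambda selection.
    seed : int
        Controls the CV fold shuffle; fits are deterministic given it.
    rule : {"min", "1se"}
        Pick the CV-error-minimizing lambda, or the sparsest lambda within
        one standard error of it (the usual parsimony rule).

    Returns
    -------
    ndarray, shape (a, b)
        Coefficient matrix; column j solves the penalized problem for
        response j at its CV-selected lambda.
    """
    X = np.asarray(predictors, float)
    Y = np.asarray(responses, float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n, a = X.shape
    b = Y.shape[1]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite values in predictors or responses")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, Y, alpha)
    grid = np.asarray(lambda_grid, float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if np.abs(X).max() == 0:
        return np.zeros((a, b)) if not squeeze else np.zeros(a)
    grid = np.sort(grid)[::-1]

    if grid.size == 1:
        model = _fit_at(X, Y, grid[0], alpha, tol=tol)
        out = _coef_matrix(model, a, b)
    elif alpha == 0.0:
        out = _cv_fit_ridge(X, Y, grid, cv_folds, seed)
    else:
        out = _cv_fit_enet(X, Y, alpha, grid, cv_folds, seed, tol, rule)
    return out[:, 0] if squeeze else out


@dataclass
class RegulationFit:
    """Estimated regulation coefficients and predicted layers."""

    beta1: np.ndarray  # r x p, CNV -> GE
    beta2: np.ndarray  # p x q, GE -> protein
    Y_hat: np.ndarray  # n x p
    Z_hat: np.ndarray  # n x q
    alpha: float = 0.5
    lambda_grid: np.ndarray | None = field(default=None, repr=False)


def predicted_layers(
    data: MultiLayerData,
    alpha: float = 0.5,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    rule: str = "min",
) -> RegulationFit:
    """Estimate both regulation models and return the predicted layers.

    Layers are column-standardized before fitting, and predictions are on
    that standardized scale (the scale the weight matrices use).
    """
    Xs = standardize_columns(data.X)
    Ys = standardize_columns(data.Y)
    Zs = standardize_columns(data.Z)
    beta1 = fit_enet_layer(Xs, Ys, alpha, lambda_grid, cv_folds, seed, rule=rule)
    beta2 = fit_enet_layer(Ys, Zs, alpha, lambda_grid, cv_folds, seed + 1, rule=rule)
    return RegulationFit(
        beta1=beta1,
        beta2=beta2,
        Y_hat=Xs @ beta1,
        Z_hat=Ys @ beta2,
        alpha=alpha,
        lambda_grid=None if lambda_grid is None else np.asarray(lambda_grid),
    )
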