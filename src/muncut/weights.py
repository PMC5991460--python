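"""Gaussian-kernel similarity matrices within and across omics layers.

Within a layer, the similarity between variables j and l is the Gaussian
kernel of their column vectors over subjects,

    w_jl = exp(-||v_j - v_l||^2 / (sigma * s)),

where ``s = n`` when ``scale_by_n`` is on (so that sigma is comparable
across sample sizes; for standardized columns the scaled squared distance
equals ``2 (1 - cor(v_j, v_l))``) and ``s = 1`` otherwise.

Across layers, similarities are computed between the *predicted*
gene-expression and protein columns (from the regulatory regressions) and
assembled into the m x m block matrix

        [   0      W_{Zhat:Yhat}    0     ]
    W~ = [ W'_{Zhat:Yhat}   0   W_{Yhat:X}]
        [   0      W'_{Yhat:X}     0      ]

with block order (proteins, gene expressions, CNVs); all within-layer
blocks and the diagonal are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data import MultiLayerData

#: Divide squared column distances by n before applying the kernel.  With
#: this on (the package default), standardized columns give weights
#: exp(-2(1 - cor)/sigma), independent of the number of subjects.
DEFAULT_SCALE_BY_N = True

#: default bandwidth of the correlation-scale kernel: at sigma = 0.35 a
#: correlation of 1 maps to weight 1, a correlation of 0 to exp(-2/0.35)
#: ~ 0.003, giving strong contrast between regulatory links and noise
DEFAULT_SIGMA = 0.35


def standardize_columns(M: np.ndarray) -> np.ndarray:
    """Center and scale each column to mean 0, sd 1 (population sd).

    Constant columns map to all-zero columns rather than dividing by zero.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = M.mean(axis=0)
    sd = M.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    out = (M - mean) / safe
    out[:, sd == 0] = 0.0
    return out


def _check_sigma(sigma: float) -> None:
    if not sigma > 0:
        raise ValueError("sigma must be positive")


def _kernel(D2: np.ndarray, sigma: float, n: int, scale_by_n: bool) -> np.ndarray:
    denom = sigma * (n if scale_by_n else 1)
    return np.exp(-D2 / denom)


#: effective correlation assigned to (null column, informative column)
#: pairs; see _null_adjusted_sqdist
DEFAULT_NULL_COR = 0.25


def _null_adjusted_sqdist(
    A: np.ndarray, B: np.ndarray, null_cor: float = DEFAULT_NULL_COR
) -> np.ndarray:
    """Squared column distances with an association-faithful null rule.

    An all-zero column (a constant variable after standardization, e.g. a
    regression prediction with every coefficient zero) carries no
    association signal.  Geometrically, however, the zero vector is
    *closer* to every real column (squared distance ||v||^2) than
    uncorrelated standardized columns are to each other (2 ||v||^2), so a
    plain kernel would treat "no evidence" as "half-way similar" -- as
    similar as a correlation of 0.5.  Here the distance between a null
    column and a non-null column v is set to 2 (1 - null_cor) ||v||^2,
    i.e. the null column acts like a vector of matching norm at
    correlation ``null_cor`` with every informative column; two null
    columns remain at distance 0 (identical).  The default 0.25 places
    "no prediction" well below genuine regulatory similarity while
    keeping variables with null predictions mildly attracted to each
    other's neighborhoods rather than free-floating.
    """
    if not 0.0 <= null_cor < 1.0:
        raise ValueError("null_cor must be in [0, 1)")
    D2 = cdist(A.T, B.T, metric="sqeuclidean")
    na = (A != 0).any(axis=0)
    nb = (B != 0).any(axis=0)
    scale = 2.0 * (1.0 - null_cor)
    if not na.all():
        D2[np.ix_(~na, nb)] = scale * (B[:, nb] ** 2).sum(axis=0)[None, :]
    if not nb.all():
        D2[np.ix_(na, ~nb)] = scale * (A[:, na] ** 2).sum(axis=0)[:, None]
    return D2


def within_layer_weights(
    L: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    scale_by_n: bool = DEFAULT_SCALE_BY_N,
    null_cor: float = DEFAULT_NULL_COR,
) -> np.ndarray:
    """Gaussian-kernel similarity between all column pairs of one layer.

    Returns a symmetric d x d matrix with unit diagonal and entries in
    (0, 1].
    """
    _check_sigma(sigma)
    L = np.asarray(L, dtype=float)
    D2 = _null_adjusted_sqdist(L, L, null_cor)
    W = _kernel(D2, sigma, L.shape[0], scale_by_n)
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 1.0)
    return W


def cross_layer_block(
    A: np.ndarray,
    B: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    scale_by_n: bool = DEFAULT_SCALE_BY_N,
    null_cor: float = DEFAULT_NULL_COR,
) -> np.ndarray:
    """Kernel similarities between columns of A and columns of B."""
    _check_sigma(sigma)
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("layers must share the subject dimension")
    D2 = _null_adjusted_sqdist(A, B, null_cor)
    return _kernel(D2, sigma, A.shape[0], scale_by_n)


def cross_layer_weights(
    Z_hat: np.ndarray,
    Y_hat: np.ndarray,
    X: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    scale_by_n: bool = DEFAULT_SCALE_BY_N,
    null_cor: float = DEFAULT_NULL_COR,
) -> np.ndarray:
    """Assemble the m x m cross-layer block weight matrix.

    ``Z_hat`` and ``Y_hat`` are the predicted protein and gene-expression
    layers; ``X`` is the observed CNV layer.  Only the (protein, GE) and
    (GE, CNV) blocks are nonzero; the result is symmetric with zero
    diagonal.
    """
    n = Z_hat.shape[0]
    if Y_hat.shape[0] != n or X.shape[0] != n:
        raise ValueError("Z_hat, Y_hat and X must share the subject dimension")
    q, p, r = Z_hat.shape[1], Y_hat.shape[1], X.shape[1]
    m = q + p + r
    W_zy = cross_layer_block(Z_hat, Y_hat, sigma, scale_by_n, null_cor)  # q x p
    W_yx = cross_layer_block(Y_hat, X, sigma, scale_by_n, null_cor)  # p x r
    W = np.zeros((m, m))
    W[:q, q : q + p] = W_zy
    W[q : q + p, :q] = W_zy.T
    W[q : q + p, q + p :] = W_yx
    W[q + p :, q : q + p] = W_yx.T
    return W


@dataclass
class WeightSet:
    """Within-layer similarity matrices plus the cross-layer block matrix.

    ``W_C``, ``W_G`` and ``W_P`` are r x r, p x p and q x q Gaussian-kernel
    matrices on the observed layers.  ``W_mega`` is the m x m cross-layer
    matrix built from the predicted layers.
    """

    W_C: np.ndarray
    W_G: np.ndarray
    W_P: np.ndarray
    W_mega: np.ndarray
    sigma: float = 1.0
    scale_by_n: bool = DEFAULT_SCALE_BY_N
    diag_included: bool = False

    @property
    def m(self) -> int:
        return self.W_mega.shape[0]

    def within_blockdiag(self) -> np.ndarray:
        """m x m block-diagonal matrix of the within-layer weights.

        Blocks follow the mega order (P, G, C).  Used for evaluating the
        single-layer NCut on a full mega-vector partition.
        """
        q = self.W_P.shape[0]
        p = self.W_G.shape[0]
        r = self.W_C.shape[0]
        W = np.zeros((q + p + r, q + p + r))
        W[:q, :q] = self.W_P
        W[q : q + p, q : q + p] = self.W_G
        W[q + p :, q + p :] = self.W_C
        return W


def build_weights(
    data: MultiLayerData,
    Y_hat: np.ndarray,
    Z_hat: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    scale_by_n: bool = DEFAULT_SCALE_BY_N,
    null_cor: float = DEFAULT_NULL_COR,
) -> WeightSet:
    """Compute all weight matrices for a dataset and its predicted layers.

    All columns (observed and predicted) are standardized before any
    kernel evaluation so that a single bandwidth is meaningful across
    layers of different scales.
    """
    Xs = standardize_columns(data.X)
    Ys = standardize_columns(data.Y)
    Zs = standardize_columns(data.Z)
    Yhs = standardize_columns(Y_hat)
    Zhs = standardize_columns(Z_hat)
    return WeightSet(
        W_C=within_layer_weights(Xs, sigma, scale_by_n, null_cor),
        W_G=within_layer_weights(Ys, sigma, scale_by_n, null_cor),
        W_P=within_layer_weights(Zs, sigma, scale_by_n, null_cor),
        W_mega=cross_layer_weights(Zhs, Yhs, Xs, sigma, scale_by_n, null_cor),
        sigma=sigma,
        scale_by_n=scale_by_n,
    )
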