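"""Synthetic multilayer datasets with known regulatory-channel structure.

Each dataset has equal layer sizes q = p = r and four true clusters whose
per-layer sizes are (q/5, 2q/5, q/5, q/5).  CNVs are multivariate normal
with unit variances and a block covariance; gene expressions and proteins
follow the linear regulation models

    Y = X b1 + e1,    Z = Y b2 + e2,    e ~ N(0, noise_sd^2) iid,

where b1 and b2 are block-diagonal over the clusters with sparse
Unif(h/2, h) entries inside the first three blocks and an all-zero fourth
block -- cluster four is a pure-noise cluster with no within-layer
correlation and no cross-layer regulation.

Covariance scenarios:

* ``I``  -- blocks 1-3 have off-diagonals rho, block 4 is identity, CNVs
  in different clusters are independent.
* ``II`` -- blocks 1-3 have off-diagonals 2*rho and *all* remaining
  off-diagonals equal rho (cross-cluster and noisy-cluster correlation).
* ``III`` -- covariance as in I, but the outcome models add unmeasured
  regulators: Y gains U1 g1 and Z gains U2 g2, with U1, U2 drawn like X
  and g1, g2 built like b1, b2, so the fitted two-layer regressions are
  mis-specified.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .data import MultiLayerData, Partition

SCENARIOS = ("I", "II", "III")


def cluster_sizes(q: int) -> list[int]:
    """Per-layer true cluster sizes (q/5, 2q/5, q/5, q/5)."""
    if q % 5 != 0 or q < 5:
        raise ValueError("q must be a positive multiple of 5")
    s = q // 5
    return [s, 2 * s, s, s]


@dataclass
class SimulationConfig:
    """Generator settings; defaults mirror the benchmark's first setting."""

    scenario: str = "I"
    n: int = 200
    q: int = 400
    h: float = 0.15
    rho: float = 0.20
    nonzero_fraction: float = 0.2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        cluster_sizes(self.q)  # validates divisibility
        if not (0 <= self.rho < 0.5):
            raise ValueError("rho must be in [0, 0.5)")
        if self.h <= 0:
            raise ValueError("h must be positive")
        if not (0 < self.nonzero_fraction <= 1):
            raise ValueError("nonzero_fraction must be in (0, 1]")


@dataclass
class SimulationTruth:
    """Generated data plus ground truth."""

    data: MultiLayerData
    true_partition: Partition
    beta1: np.ndarray
    beta2: np.ndarray
    config: SimulationConfig
    gamma1: np.ndarray | None = None  # scenario III only
    gamma2: np.ndarray | None = None


def make_covariance(scenario: str, q: int, rho: float) -> np.ndarray:
    """Block covariance of the CNV layer (unit diagonal).

    Raises ``ValueError`` if the requested matrix is not positive
    definite (possible in scenario II with large rho).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    sizes = cluster_sizes(q)
    if scenario == "II":
        sigma = np.full((q, q), rho)
    else:
        sigma = np.zeros((q, q))
    start = 0
    within = 2 * rho if scenario == "II" else rho
    for bi, s in enumerate(sizes):
        stop = start + s
        if bi < 3:
            sigma[start:stop, start:stop] = within
        else:  # noisy fourth block: independent CNVs
            if scenario != "II":
                sigma[start:stop, start:stop] = 0.0
        start = stop
    np.fill_diagonal(sigma, 1.0)
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"covariance is not positive definite (scenario {scenario}, rho={rho})"
        ) from exc
    return sigma


def make_coefficients(
    q: int,
    h: float,
    nonzero_fraction: float = 0.2,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sparse block-diagonal regulation matrix.

    Within each of the first three diagonal blocks,
    ``ceil(nonzero_fraction * s^2)`` randomly placed entries are drawn
    from Unif(h/2, h); everything else, including the whole fourth block
    and all off-block entries, is zero.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sizes = cluster_sizes(q)
    B = np.zeros((q, q))
    start = 0
    for bi, s in enumerate(sizes):
        stop = start + s
        if bi < 3:
            k = ceil(nonzero_fraction * s * s)
            flat = rng.choice(s * s, size=k, replace=False)
            block = np.zeros(s * s)
            block[flat] = rng.uniform(h / 2.0, h, size=k)
            B[start:stop, start:stop] = block.reshape(s, s)
        start = stop
    return B


def _true_partition(q: int) -> Partition:
    sizes = cluster_sizes(q)
    per_layer = np.repeat(np.arange(4), sizes)
    labels = np.concatenate([per_layer, per_layer, per_layer])
    layer_of = np.array(["P"] * q + ["G"] * q + ["C"] * q, dtype="<U1")
    return Partition(labels, layer_of, K=4)


def generate_dataset(config: SimulationConfig) -> SimulationTruth:
    """Draw one replicate under the configured scenario.

    Bitwise reproducible for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    q = config.q
    sigma = make_covariance(config.scenario, q, config.rho)
    chol = np.linalg.cholesky(sigma)

    def draw_cnv_like() -> np.ndarray:
        return rng.standard_normal((config.n, q)) @ chol.T

    X = draw_cnv_like()
    beta1 = make_coefficients(q, config.h, config.nonzero_fraction, rng)
    beta2 = make_coefficients(q, config.h, config.nonzero_fraction, rng)
    Y = X @ beta1 + config.noise_sd * rng.standard_normal((config.n, q))
    gamma1 = gamma2 = None
    if config.scenario == "III":
        U1 = draw_cnv_like()
        gamma1 = make_coefficients(q, config.h, config.nonzero_fraction, rng)
        Y = Y + U1 @ gamma1
    Z = Y @ beta2 + config.noise_sd * rng.standard_normal((config.n, q))
    if config.scenario == "III":
        U2 = draw_cnv_like()
        gamma2 = make_coefficients(q, config.h, config.nonzero_fraction, rng)
        Z = Z + U2 @ gamma2

    data = MultiLayerData(X=X, Y=Y, Z=Z)
    return SimulationTruth(
        data=data,
        true_partition=_true_partition(q),
        beta1=beta1,
        beta2=beta2,
        config=config,
        gamma1=gamma1,
        gamma2=gamma2,
    )
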