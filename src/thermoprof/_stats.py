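"""Shared statistical helpers: block averaging and nearest-neighbour entropy."""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln


def block_sem(values: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error of the mean of a correlated series by block averaging.

    The series is split into ``n_blocks`` contiguous blocks; the SEM is the
    standard deviation of the block means divided by sqrt(n_blocks).  Blocks
    longer than the correlation time make this a nearly unbiased estimate of
    the true SEM of the full-series mean.
    """
    values = np.asarray(values, dtype=float)
    if values.size < n_blocks:
        n_blocks = max(2, values.size)
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    if len(means) < 2:
        return 0.0
    return float(means.std(ddof=1) / np.sqrt(len(means)))


def block_apply_sem(values: np.ndarray, func, n_blocks: int = 10) -> float:
    """SEM of a nonlinear statistic ``func`` of a series, by block averaging.

    ``func`` is evaluated on each contiguous block; the spread of the block
    estimates gives the SEM of the full-series estimate.
    """
    values = np.asarray(values, dtype=float)
    if values.size < n_blocks:
        n_blocks = max(2, values.size)
    blocks = np.array_split(values, n_blocks)
    ests = np.array([func(b) for b in blocks])
    if len(ests) < 2:
        return 0.0
    return float(ests.std(ddof=1) / np.sqrt(len(ests)))


def _unit_ball_log_volume(d: int) -> float:
    return float(d / 2 * np.log(np.pi) - gammaln(d / 2 + 1))


def kl_entropy(points: np.ndarray) -> float:
    """Kozachenko-Leonenko differential entropy (nats) with k=1 neighbours.

    H = psi(n) - psi(1) + ln V_d + (d/n) * sum_i ln eps_i,
    where eps_i is the distance from point i to its nearest neighbour and
    V_d the d-dimensional unit-ball volume.  psi(1) = -gamma supplies the
    Grassberger-type log correction for k=1.
    """
    from scipy.spatial import cKDTree

    points = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = points.shape
    if n < 2:
        raise ValueError("entropy estimate needs at least 2 points")
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=2)
    eps = dist[:, 1]
    eps = np.maximum(eps, 1e-12)
    return float(
        digamma(n) - digamma(1) + _unit_ball_log_volume(d) + d * np.mean(np.log(eps))
    )


def sphere_nn_entropy(unit_vectors: np.ndarray) -> float:
    """Nearest-neighbour entropy (nats) of a distribution on the unit sphere.

    Uses geodesic (great-circle) nearest-neighbour angles with the d=2
    Kozachenko-Leonenko formula; for the uniform distribution this converges
    to ln(4*pi).
    """
    u = np.asarray(unit_vectors, dtype=float)
    n = u.shape[0]
    if n < 2:
        raise ValueError("entropy estimate needs at least 2 points")
    # chord nearest neighbour == geodesic nearest neighbour on the sphere
    from scipy.spatial import cKDTree

    tree = cKDTree(u)
    dist, _ = tree.query(u, k=2)
    chord = np.clip(dist[:, 1], 1e-12, 2.0)
    theta = 2.0 * np.arcsin(chord / 2.0)
    theta = np.maximum(theta, 1e-12)
    return float(digamma(n) - digamma(1) + np.log(np.pi) + 2.0 * np.mean(np.log(theta)))
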