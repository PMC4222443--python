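"""Probabilistic D-Clustering: soft p-Median by alternating Weiszfeld-type updates.

Cluster membership probability at a point is taken inversely proportional to
its distance from each cluster center; centers are then refit as convex
combinations of the data weighted by p^2/d. The two updates alternate until
the summed center movement drops below a tolerance. Hardening assigns each
point to its most probable cluster and reports the nearest data point to
each center as the cluster's median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .distance import correlation_distance
from .pmedian import ClusteringSolution

logger = logging.getLogger(__name__)


def _point_center_distances(X: np.ndarray, centers: np.ndarray, metric: str) -> np.ndarray:
    """|Omega| x K matrix of distances from each row of X to each center."""
    if metric == "euclidean":
        diff = X[:, None, :] - centers[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if metric == "correlation":
        Xc = X - X.mean(axis=1, keepdims=True)
        Cc = centers - centers.mean(axis=1, keepdims=True)
        xn = np.linalg.norm(Xc, axis=1)
        cn = np.linalg.norm(Cc, axis=1)
        if np.any(xn == 0) or np.any(cn == 0):
            raise ValueError("constant profile encountered; correlation undefined")
        corr = np.clip((Xc @ Cc.T) / np.outer(xn, cn), -1.0, 1.0)
        return 1.0 - corr
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class SoftClusteringSolution:
    """Cluster centers, per-cell membership probabilities and run diagnostics."""

    centers: np.ndarray
    probabilities: np.ndarray
    n_iterations: int
    converged: bool
    objective: float
    metric: str = "correlation"

    def __post_init__(self) -> None:
        P = np.asarray(self.probabilities, dtype=float)
        if P.min() < -1e-12:
            raise ValueError("probabilities must be non-negative")
        if np.abs(P.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("probability rows must sum to 1")
        if self.centers.shape[0] != P.shape[1]:
            raise ValueError("one center per cluster required")


def update_probabilities(X: np.ndarray, centers: np.ndarray,
                         metric: str = "correlation") -> np.ndarray:
    """Membership probabilities p_k(x_i) proportional to prod_{j!=k} d(x_i, c_j).

    Points at zero distance from a center take the limit value: probability 1
    on (the first of) the coinciding center(s), 0 elsewhere.
    """
    D = _point_center_distances(np.asarray(X, float), np.asarray(centers, float), metric)
    n, K = D.shape
    P = np.zeros((n, K))
    zero = D <= 0.0
    has_zero = zero.any(axis=1)
    for i in np.flatnonzero(has_zero):
        P[i, np.flatnonzero(zero[i])[0]] = 1.0
    rest = ~has_zero
    if rest.any():
        # prod_{j!=k} d_j = (prod_j d_j)/d_k, so p_k is proportional to 1/d_k
        inv = 1.0 / D[rest]
        P[rest] = inv / inv.sum(axis=1, keepdims=True)
    return P


def update_centers(X: np.ndarray, probabilities: np.ndarray, centers: np.ndarray,
                   metric: str = "correlation") -> np.ndarray:
    """Weiszfeld center update: convex combinations with weights p_k(x_i)^2 / d(x_i, c_k).

    Points exactly at a center are excluded from that cluster's sums (the
    probability limit rule already gives them full membership). A cluster
    whose weights all vanish keeps its center and logs a warning.
    """
    X = np.asarray(X, float)
    P = np.asarray(probabilities, float)
    centers = np.asarray(centers, float)
    D = _point_center_distances(X, centers, metric)
    new = centers.copy()
    for k in range(centers.shape[0]):
        ok = D[:, k] > 0.0
        if not ok.any():
            logger.warning("cluster %d has no positive-distance points; center kept", k)
            continue
        w = P[ok, k] ** 2 / D[ok, k]
        total = w.sum()
        if total <= 0.0:
            logger.warning("cluster %d has all-zero weights; center kept", k)
            continue
        new[k] = (w[:, None] * X[ok]).sum(axis=0) / total
    return new


def _farthest_point_init(X: np.ndarray, K: int, rng: np.random.Generator,
                         metric: str) -> np.ndarray:
    """K distinct data points: a random first pick, then greedy max-min distance."""
    n = X.shape[0]
    chosen = [int(rng.integers(n))]
    while len(chosen) < K:
        D = _point_center_distances(X, X[chosen], metric)
        mind = D.min(axis=1)
        mind[chosen] = -np.inf
        chosen.append(int(np.argmax(mind)))
    return X[chosen].copy()


def solve_pdclustering(
    X: np.ndarray,
    K: int,
    epsilon: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    metric: str = "correlation",
) -> SoftClusteringSolution:
    """Alternate probability and center updates from a farthest-point start.

    Stops when the summed Euclidean center movement falls below ``epsilon``
    or after ``max_iter`` iterations; the returned objective is
    sum_ik p_k(x_i)^2 d(x_i, c_k).
    """
    X = np.asarray(X, float)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not 1 <= K <= X.shape[0]:
        raise ValueError(f"K must be in [1, {X.shape[0]}], got {K}")
    rng = np.random.default_rng(seed)
    centers = _farthest_point_init(X, K, rng, metric)
    converged = False
    P = update_probabilities(X, centers, metric)
    it = 0
    for it in range(1, max_iter + 1):
        P = update_probabilities(X, centers, metric)
        new = update_centers(X, P, centers, metric)
        move = float(np.linalg.norm(new - centers, axis=1).sum())
        centers = new
        if move < epsilon:
            converged = True
            break
    P = update_probabilities(X, centers, metric)
    D = _point_center_distances(X, centers, metric)
    objective = float((P**2 * D).sum())
    return SoftClusteringSolution(
        centers=centers,
        probabilities=P,
        n_iterations=it,
        converged=converged,
        objective=objective,
        metric=metric,
    )


def harden(soft: SoftClusteringSolution, X: np.ndarray) -> ClusteringSolution:
    """Hard assignment: each cell to its most probable cluster (ties: lowest index).

    Medians are the data points nearest each center under the run's metric;
    the reported objective is the summed distance of every cell to its
    cluster's median.
    """
    X = np.asarray(X, float)
    labels = np.argmax(soft.probabilities, axis=1)  # argmax takes the lowest index on ties
    d_to_center = _point_center_distances(X, soft.centers, soft.metric)
    medians_per_cluster = np.argmin(d_to_center, axis=0)
    assignment = medians_per_cluster[labels]
    # medians must be self-assigned and distinct; duplicates collapse clusters
    uniq = sorted(set(int(m) for m in assignment))
    for m in uniq:
        assignment[m] = m
    if soft.metric == "euclidean":
        dists = np.sqrt(((X - X[assignment]) ** 2).sum(axis=1))
        objective = float(dists.sum())
    else:
        objective = float(
            sum(
                0.0 if i == a else correlation_distance(X[i], X[a])
                for i, a in enumerate(assignment)
            )
        )
    return ClusteringSolution(
        medians=uniq,
        assignment=assignment,
        objective_primary=objective,
        K=len(uniq),
    )
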