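"""Fuzzy c-means clustering of reconstructed state vectors.

Standard FCM (Bezdek): memberships u_ik in [0,1] with rows summing to 1,
centers v_i as membership-weighted means, alternated from a seeded random
membership initialization until the centers stop moving.  The objective

    J = sum_k sum_i  u_ik^m  ||x_k - v_i||^2

is non-increasing across iterations (each half-update minimizes J in its
block).  Euclidean distance throughout; fuzzifier default m = 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class ClusterModel:
    """A fitted FCM model: centers, fuzzy memberships and the fit trace."""

    centers: np.ndarray          # (C, M)
    membership: np.ndarray       # (K, C), rows sum to 1
    fuzzifier: float
    n_iter: int
    objective_trace: np.ndarray  # (n_iter,)
    seed: int

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


def choose_cluster_count(n_vectors: int, cap: int = 20) -> int:
    """Default cluster count: min(cap, floor(sqrt(K))).

    The square-root rule bounds C by the data size; the cap (default 20)
    keeps clusters populated enough to contain several near-identical
    state recurrences.
    """
    if n_vectors < 2:
        raise ValueError("need at least 2 vectors to cluster")
    return min(cap, math.floor(math.sqrt(n_vectors)))


def _memberships(d2: np.ndarray, fuzzifier: float) -> np.ndarray:
    """Membership update from squared distances; zero distances get full
    membership on their (first) coincident center."""
    exp = 1.0 / (fuzzifier - 1.0)
    zero_rows = np.any(d2 <= 0.0, axis=1)
    with np.errstate(divide="ignore", over="ignore"):
        w = d2 ** (-exp)
    u = np.empty_like(d2)
    ok = ~zero_rows
    u[ok] = w[ok] / w[ok].sum(axis=1, keepdims=True)
    if np.any(zero_rows):
        u[zero_rows] = 0.0
        first_zero = np.argmax(d2[zero_rows] <= 0.0, axis=1)
        u[np.nonzero(zero_rows)[0], first_zero] = 1.0
    return u


def fcm_fit(vectors: np.ndarray, C: int, fuzzifier: float = 2.0,
            tol: float = 1e-5, max_iter: int = 300, seed: int = 0) -> ClusterModel:
    """Fit fuzzy c-means to a (K, M) matrix of state vectors.

    Deterministic for a fixed seed.  Convergence is declared when the
    largest coordinate-wise center displacement falls below ``tol``.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("vectors must be a 2-D (K, M) matrix")
    K = X.shape[0]
    if not 1 <= C <= K:
        raise ValueError(f"C={C} must satisfy 1 <= C <= K={K}")
    if fuzzifier <= 1.0:
        raise ValueError("fuzzifier must be > 1")
    if tol <= 0:
        raise ValueError("tol must be positive")

    if C == 1:
        center = X.mean(axis=0, keepdims=True)
        d2 = ((X - center) ** 2).sum(axis=1)
        return ClusterModel(centers=center, membership=np.ones((K, 1)),
                            fuzzifier=fuzzifier, n_iter=0,
                            objective_trace=np.array([float(d2.sum())]), seed=seed)

    rng = np.random.default_rng(seed)
    u = rng.random((K, C))
    u /= u.sum(axis=1, keepdims=True)

    centers = np.empty((C, X.shape[1]))
    prev_centers = None
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        um = u ** fuzzifier
        denom = um.sum(axis=0)
        # a cluster with (numerically) zero total membership keeps its center
        safe = denom > 0
        new_centers = centers.copy() if prev_centers is not None else np.zeros_like(centers)
        new_centers[safe] = (um.T[safe] @ X) / denom[safe, None]
        centers = new_centers
        d2 = cdist(X, centers, metric="sqeuclidean")
        u = _memberships(d2, fuzzifier)
        trace.append(float(((u ** fuzzifier) * d2).sum()))
        if prev_centers is not None and np.max(np.abs(centers - prev_centers)) < tol:
            break
        prev_centers = centers.copy()

    return ClusterModel(centers=centers, membership=u, fuzzifier=fuzzifier,
                        n_iter=n_iter, objective_trace=np.asarray(trace), seed=seed)


def hard_assign(model: ClusterModel) -> np.ndarray:
    """Crisp labels: argmax membership per row, ties to the lowest index."""
    return np.argmax(model.membership, axis=1)
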