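"""Clustering and coarse-graining of the cell-level Markov chain.

Cells are partitioned into K metastable clusters (k-means on the
embedding) and the cell-level transition matrix P is aggregated into

* P_hat_raw[s, t] = mu_hat_t / (n_s n_t) * sum_{i in s} sum_{j in t} P_ij,
  the coarse transition matrix (row-normalised into P_hat before use,
  since the raw aggregate is only approximately row-stochastic at
  finite sample size);
* L_hat = (P_hat - I)/epsilon, the coarse backward operator;
* P_tilde[s, t] = sum_{i in s} sum_{j in t} mu_i P_ij, the symmetric
  edge-weight matrix whose nonzero off-diagonals are candidate
  differentiation paths.

Guidance on K: at least (number of lineages + 2) — one cluster for the
stem population, one near each bifurcation, one per branch — and at most
the number of metastable wells; merging two non-bifurcation neighbours
does not change the pseudo-time order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .preprocess import Embedding

__all__ = [
    "ClusterModel",
    "cluster_cells",
    "coarse_transition",
    "coarse_backward",
    "cluster_weight_matrix",
    "build_cluster_model",
]


@dataclass
class ClusterModel:
    """Cluster partition plus all coarse matrices."""

    labels: np.ndarray
    K: int
    n_s: np.ndarray
    mu_hat: np.ndarray
    P_hat_raw: np.ndarray
    P_hat: np.ndarray
    L_hat: np.ndarray
    P_tilde: np.ndarray
    epsilon: float


def cluster_cells(E: Embedding | np.ndarray, K: int, seed: int = 0,
                  n_init: int = 10) -> np.ndarray:
    """k-means labels in {0..K-1}, deterministic given seed; cluster
    indices are relabelled in order of descending size (ties by lower
    original index) for stability across runs."""
    coords = E.coords if isinstance(E, Embedding) else np.asarray(E, dtype=float)
    n = coords.shape[0]
    if not 2 <= K <= n:
        raise ValueError(f"K must be in [2, n], got K={K}, n={n}")
    n_distinct = np.unique(coords, axis=0).shape[0]
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds the {n_distinct} distinct points")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    raw = km.fit_predict(coords)
    sizes = np.bincount(raw, minlength=K)
    order = np.lexsort((np.arange(K), -sizes))
    remap = np.empty(K, dtype=int)
    remap[order] = np.arange(K)
    return remap[raw]


def _indicator(labels: np.ndarray, K: int) -> np.ndarray:
    C = np.zeros((len(labels), K))
    C[np.arange(len(labels)), labels] = 1.0
    return C


def coarse_transition(P: np.ndarray, mu: np.ndarray, labels: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coarse-grained transition matrix between clusters.

    Returns ``(mu_hat, P_hat_raw, P_hat)`` where ``P_hat_raw`` is the
    exact aggregate and ``P_hat`` its row-normalised version (rows sum
    to 1, so constants are in the null space of P_hat - I).
    """
    labels = np.asarray(labels)
    K = int(labels.max()) + 1
    n_s = np.bincount(labels, minlength=K)
    if (n_s == 0).any():
        raise ValueError(f"empty cluster(s): {np.nonzero(n_s == 0)[0].tolist()}")
    C = _indicator(labels, K)
    mu_hat = C.T @ mu
    block = C.T @ P @ C  # sum_{i in s} sum_{j in t} P_ij
    P_hat_raw = block * mu_hat[None, :] / np.outer(n_s, n_s)
    P_hat = P_hat_raw / P_hat_raw.sum(axis=1, keepdims=True)
    return mu_hat, P_hat_raw, P_hat


def coarse_backward(P_hat: np.ndarray, epsilon: float) -> np.ndarray:
    """L_hat = (P_hat - I) / epsilon."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return (np.asarray(P_hat, dtype=float) - np.eye(P_hat.shape[0])) / epsilon


def cluster_weight_matrix(P: np.ndarray, mu: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """P_tilde[s, t] = sum_{i in s} sum_{j in t} mu_i P_ij.

    Symmetric for a reversible chain (mu_i P_ij = mu_j P_ji) and sums
    to 1 over all entries.
    """
    labels = np.asarray(labels)
    K = int(labels.max()) + 1
    C = _indicator(labels, K)
    return C.T @ (mu[:, None] * P) @ C


def build_cluster_model(E: Embedding, P: np.ndarray, mu: np.ndarray,
                        epsilon: float, K: int, seed: int = 0,
                        labels: np.ndarray | None = None) -> ClusterModel:
    """Cluster the embedding (or use given labels) and assemble all
    coarse matrices."""
    if labels is None:
        labels = cluster_cells(E, K, seed)
    labels = np.asarray(labels)
    K = int(labels.max()) + 1
    mu_hat, P_hat_raw, P_hat = coarse_transition(P, mu, labels)
    return ClusterModel(
        labels=labels,
        K=K,
        n_s=np.bincount(labels, minlength=K),
        mu_hat=mu_hat,
        P_hat_raw=P_hat_raw,
        P_hat=P_hat,
        L_hat=coarse_backward(P_hat, epsilon),
        P_tilde=cluster_weight_matrix(P, mu, labels),
        epsilon=epsilon,
    )
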