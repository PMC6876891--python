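"""Anisotropic diffusion-map construction of the backward operator.

From an embedding of N cells this module builds a kNN-sparsified
Gaussian kernel W, applies the anisotropic normalisation with exponent
alpha (alpha = 1/2 by default), and forms the row-stochastic transition
matrix P, its stationary distribution mu and the discrete backward
Kolmogorov operator L = (P - I)/epsilon.

With alpha = 1/2 and density-sampled points, L converges (N -> inf,
epsilon -> 0) to the generator  grad(log r) . grad + Laplacian  of the
underlying diffusion regardless of the sampling density r — this is the
operator the potential equation is solved against downstream.

Conventions: kernel K_eps(x, y) = (4 pi eps)^(-m/2) exp(-|x-y|^2 / 4 eps);
the bandwidth is set so that 2*eps equals the median pairwise Euclidean
distance; kNN edges are symmetrised with the union (OR) rule and
self-loops are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NearestNeighbors

from .preprocess import Embedding

__all__ = [
    "DiffusionModel",
    "gaussian_kernel",
    "median_bandwidth",
    "build_knn_graph",
    "anisotropic_transition",
    "backward_operator",
    "equilibrium_potential",
    "build_diffusion_model",
]


@dataclass
class DiffusionModel:
    """Cell-level Markov model: kernel graph W, transition matrix P,
    stationary distribution mu, bandwidth epsilon and operator L."""

    P: np.ndarray
    mu: np.ndarray
    epsilon: float
    alpha: float
    knn_k: int
    W: np.ndarray
    L: np.ndarray


def gaussian_kernel(x: np.ndarray, y: np.ndarray, epsilon: float, m: int | None = None) -> float:
    """K_eps(x, y) = (4 pi eps)^(-m/2) exp(-|x - y|^2 / (4 eps))."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if m is None:
        m = x.shape[-1]
    d2 = float(np.sum((x - y) ** 2))
    return (4.0 * np.pi * epsilon) ** (-m / 2.0) * np.exp(-d2 / (4.0 * epsilon))


def median_bandwidth(E: Embedding | np.ndarray) -> float:
    """epsilon = median(pairwise distances) / 2, i.e. the kernel width
    2*epsilon equals the median inter-cell distance."""
    coords = E.coords if isinstance(E, Embedding) else np.asarray(E, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 points")
    med = float(np.median(pdist(coords)))
    if med <= 0:
        raise ValueError("zero median distance: all points identical")
    return med / 2.0


def build_knn_graph(E: Embedding | np.ndarray, k: int, epsilon: float,
                    symmetrization: str = "or") -> np.ndarray:
    """Symmetric kernel weight matrix on the kNN graph.

    W_ij = K_eps(x_i, x_j) if j is among i's k nearest neighbours or
    (OR rule) i among j's, else 0; the diagonal self-weight is kept.
    ``symmetrization='and'`` keeps only mutual neighbours.
    """
    coords = E.coords if isinstance(E, Embedding) else np.asarray(E, dtype=float)
    n, m = coords.shape
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, n-1], got k={k}, n={n}")
    if symmetrization not in ("or", "and"):
        raise ValueError("symmetrization must be 'or' or 'and'")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    # +1 because the query point itself is its own nearest neighbour
    idx = nn.kneighbors(coords, return_distance=False)
    A = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), idx.shape[1])
    A[rows, idx.ravel()] = True
    np.fill_diagonal(A, True)
    A = (A | A.T) if symmetrization == "or" else (A & A.T)
    d2 = squareform(pdist(coords, "sqeuclidean"))
    W = (4.0 * np.pi * epsilon) ** (-m / 2.0) * np.exp(-d2 / (4.0 * epsilon))
    W[~A] = 0.0
    return W


def anisotropic_transition(W: np.ndarray, alpha: float = 0.5,
                           cell_ids: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Density-corrected transition matrix and stationary distribution.

    q_i = sum_j W_ij;  K^(a)_ij = W_ij / (q_i^a q_j^a);
    d_i = sum_j K^(a)_ij;  P_ij = K^(a)_ij / d_i;  mu_i = d_i / sum d.

    K^(a) stays symmetric, so the chain is reversible and mu P = mu.
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("kernel weights must be nonnegative")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("W must be symmetric")
    q = W.sum(axis=1)
    zero = q <= 0
    if zero.any():
        i = int(np.argmax(zero))
        name = cell_ids[i] if cell_ids else f"index {i}"
        raise ValueError(
            f"isolated cell with no kernel weight: {name}; increase knn_k"
        )
    Ka = W / np.outer(q**alpha, q**alpha)
    d = Ka.sum(axis=1)
    P = Ka / d[:, None]
    mu = d / d.sum()
    return P, mu


def backward_operator(P: np.ndarray, epsilon: float) -> np.ndarray:
    """Discrete backward Kolmogorov operator L = (P - I) / epsilon."""
    P = np.asarray(P, dtype=float)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return (P - np.eye(P.shape[0])) / epsilon


def equilibrium_potential(E: Embedding | np.ndarray, D: float, epsilon: float) -> np.ndarray:
    """Per-cell equilibrium potential U_i = -D log p_hat(x_i), with
    p_hat a Gaussian kernel density estimate of bandwidth tied to the
    diffusion kernel (variance 2*epsilon per axis).

    U has wells at density modes: it is the part of the potential caused
    by diffusion alone, complementary to the advection potential solved
    for downstream.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    coords = E.coords if isinstance(E, Embedding) else np.asarray(E, dtype=float)
    n, m = coords.shape
    d2 = squareform(pdist(coords, "sqeuclidean"))
    dens = ((4.0 * np.pi * epsilon) ** (-m / 2.0) * np.exp(-d2 / (4.0 * epsilon))).mean(axis=1)
    return -D * np.log(dens)


def build_diffusion_model(E: Embedding, *, epsilon: float | None = None,
                          alpha: float = 0.5, knn_k: int | None = None,
                          symmetrization: str = "or") -> DiffusionModel:
    """Convenience constructor running the full kernel -> P -> mu -> L chain."""
    n = E.n_cells
    if knn_k is None:
        knn_k = min(n - 1, 15)
    if epsilon is None:
        epsilon = median_bandwidth(E)
    W = build_knn_graph(E, knn_k, epsilon, symmetrization)
    n_comp, _ = connected_components(csr_matrix(W > 0), directed=False)
    if n_comp > 1:
        raise ValueError(
            f"kNN kernel graph has {n_comp} connected components; the "
            "stationary distribution is not unique — increase knn_k"
        )
    P, mu = anisotropic_transition(W, alpha, E.cell_ids)
    L = backward_operator(P, epsilon)
    return DiffusionModel(P=P, mu=mu, epsilon=epsilon, alpha=alpha,
                          knn_k=knn_k, W=W, L=L)
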