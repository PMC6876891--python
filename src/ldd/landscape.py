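"""Cluster potential, pseudo-time, differentiation paths and surface.

The cluster potential solves the discrete potential equation
``(P_hat - I) V_hat = -R_tilde * epsilon``.  The left-hand matrix is
singular (constants are in its null space), so the minimum-norm
least-squares solution is taken via the Moore-Penrose pseudo-inverse:

    V_hat = -pinv(P_hat - I) @ R_tilde * epsilon.

Interpretation: high potential = high potency.  The root cluster
(pluripotent population, maximal V_hat) is a source; differentiated
clusters sit at low potential.  Pseudo-time is the additive inverse of
the potential, so the root has the *smallest* pseudo-time and terminal
cells the largest, and correlation with true time is expected positive.

Differentiation paths: off-diagonal entries of the symmetric weight
matrix P_tilde above a threshold become edges, each oriented from its
higher-potential endpoint to its lower one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "LandscapeResult",
    "SurfaceSpec",
    "solve_potential",
    "assign_pseudotime",
    "build_paths",
    "landscape_surface",
    "evaluate_correlation",
    "wilcoxon_stage_test",
]

logger = logging.getLogger(__name__)


@dataclass
class LandscapeResult:
    """Potential, pseudo-time and directed path structure."""

    V_hat: np.ndarray
    pseudotime: np.ndarray
    edges: list[tuple[int, int, float]]
    threshold: float
    root_cluster: int
    residual: float = float("nan")


@dataclass
class SurfaceSpec:
    """Parameters of the illustrative 3-D landscape surface.

    V(x, y) = a*f(x, y) + b*g(x, y) on a grid, where f is a sum of
    inverted Gaussians of width sigma / p_tilde_i centred on the cells
    (p_tilde_i = the diagonal weight P_tilde[s, s] of cell i's cluster,
    so cells of heavy metastable clusters dig wider wells) and g is a
    monotone-in-potential trend, here the least-squares plane fitted to
    the per-cell potential.  ``cap``: grid values above it become NaN.
    """

    grid_size: int = 100
    margin: float = 0.5
    sigma: float = 0.05
    a: float = 1.0
    b: float = 1.0
    cap: float | None = None
    extent: tuple[float, float, float, float] | None = None


def solve_potential(P_hat: np.ndarray, R_tilde: np.ndarray, epsilon: float) -> np.ndarray:
    """Minimum-norm least-squares potential
    V_hat = -pinv(P_hat - I) @ R_tilde * epsilon."""
    P_hat = np.asarray(P_hat, dtype=float)
    R_tilde = np.asarray(R_tilde, dtype=float)
    if not (np.isfinite(P_hat).all() and np.isfinite(R_tilde).all()):
        raise ValueError("non-finite inputs to the potential solve")
    A = P_hat - np.eye(P_hat.shape[0])
    return -np.linalg.pinv(A) @ R_tilde * epsilon


def potential_residual(P_hat: np.ndarray, R_tilde: np.ndarray, epsilon: float,
                       V_hat: np.ndarray) -> float:
    """Norm of the defect of the potential equation at V_hat."""
    A = np.asarray(P_hat) - np.eye(len(V_hat))
    return float(np.linalg.norm(A @ V_hat + np.asarray(R_tilde) * epsilon))


def assign_pseudotime(V_hat: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-cell pseudo-time = -V_hat of the cell's cluster."""
    V_hat = np.asarray(V_hat, dtype=float)
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= len(V_hat):
        raise ValueError("labels outside the cluster range")
    return -V_hat[labels]


def build_paths(P_tilde: np.ndarray, V_hat: np.ndarray,
                threshold: float | None = None,
                n_s: np.ndarray | None = None
                ) -> tuple[list[tuple[int, int, float]], int]:
    """Directed differentiation edges and the root cluster.

    Candidate edges are off-diagonal P_tilde entries above ``threshold``
    (default: 1% of the largest off-diagonal weight); each is oriented
    from the higher-V_hat endpoint to the lower.  Ties in V_hat orient
    from the larger cluster to the smaller (with a warning).  If the
    retained graph is disconnected a warning lists per-component roots.
    """
    P_tilde = np.asarray(P_tilde, dtype=float)
    V_hat = np.asarray(V_hat, dtype=float)
    K = len(V_hat)
    off = P_tilde - np.diag(np.diag(P_tilde))
    if threshold is None:
        threshold = 0.01 * off.max() if off.max() > 0 else 0.0
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    edges: list[tuple[int, int, float]] = []
    G = nx.Graph()
    G.add_nodes_from(range(K))
    for s in range(K):
        for t in range(s + 1, K):
            w = 0.5 * (off[s, t] + off[t, s])
            if w > threshold:
                if V_hat[s] > V_hat[t]:
                    hi, lo = s, t
                elif V_hat[t] > V_hat[s]:
                    hi, lo = t, s
                else:
                    big = s if (n_s is None or n_s[s] >= n_s[t]) else t
                    hi, lo = big, s + t - big
                    logger.warning(
                        "potential tie between clusters %d and %d; oriented "
                        "from the larger cluster", s, t,
                    )
                edges.append((hi, lo, float(w)))
                G.add_edge(s, t)
    root = int(np.argmax(V_hat))
    comps = list(nx.connected_components(G))
    if len(comps) > 1:
        roots = [int(max(c, key=lambda s: V_hat[s])) for c in comps]
        logger.warning(
            "path graph disconnected (%d components); per-component roots: %s",
            len(comps), roots,
        )
    return edges, root


def maximum_weight_tree(P_tilde: np.ndarray, V_hat: np.ndarray
                        ) -> tuple[list[tuple[int, int, float]], int]:
    """Maximum-weight spanning tree of the cluster weight graph,
    oriented downhill in potential.

    A deterministic, threshold-free alternative to :func:`build_paths`
    for landscapes expected to be tree-shaped (every differentiation
    hierarchy): keeps the K-1 heaviest edges that connect all clusters.
    Returns ``(edges, root_cluster)`` with edges as (from, to, weight).
    """
    P_tilde = np.asarray(P_tilde, dtype=float)
    V_hat = np.asarray(V_hat, dtype=float)
    K = len(V_hat)
    G = nx.Graph()
    G.add_nodes_from(range(K))
    for s in range(K):
        for t in range(s + 1, K):
            w = 0.5 * (P_tilde[s, t] + P_tilde[t, s])
            if w > 0:
                G.add_edge(s, t, weight=w)
    T = nx.maximum_spanning_tree(G, weight="weight")
    edges = []
    for s, t, data in T.edges(data=True):
        hi, lo = (s, t) if V_hat[s] >= V_hat[t] else (t, s)
        edges.append((hi, lo, float(data["weight"])))
    return edges, int(np.argmax(V_hat))


def fit_linear_trend(coords_2d: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Least-squares plane coefficients (c0, cx, cy) for values ~ x, y."""
    A = np.column_stack([np.ones(len(coords_2d)), coords_2d[:, 0], coords_2d[:, 1]])
    coef, *_ = np.linalg.lstsq(A, values, rcond=None)
    return coef


def landscape_surface(coords_2d: np.ndarray, labels: np.ndarray,
                      P_tilde: np.ndarray, V_hat: np.ndarray,
                      params: SurfaceSpec | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the illustrative surface V(x, y) = a f + b g on a grid.

    Returns ``(gx, gy, V)`` with ``V[i, j]`` at ``(gx[j], gy[i])``.
    f(x,y) = mean_i -exp(-((x-x_i)^2 + (y-y_i)^2) / (sigma/p_tilde_i)^2);
    cells whose cluster has zero diagonal weight get the smallest
    positive diagonal instead (logged).
    """
    params = params or SurfaceSpec()
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    if params.grid_size < 2:
        raise ValueError("grid must have at least 2 points per axis")
    coords_2d = np.asarray(coords_2d, dtype=float)
    labels = np.asarray(labels)
    diag = np.diag(np.asarray(P_tilde, dtype=float))
    pos = diag[diag > 0]
    if len(pos) == 0:
        raise ValueError("P_tilde has no positive diagonal entries")
    if (diag <= 0).any():
        logger.warning(
            "clusters %s have zero diagonal weight; using min positive",
            np.nonzero(diag <= 0)[0].tolist(),
        )
    p_cell = np.where(diag[labels] > 0, diag[labels], pos.min())
    if params.extent is not None:
        x0, x1, y0, y1 = params.extent
    else:
        x0, x1 = coords_2d[:, 0].min() - params.margin, coords_2d[:, 0].max() + params.margin
        y0, y1 = coords_2d[:, 1].min() - params.margin, coords_2d[:, 1].max() + params.margin
    gx = np.linspace(x0, x1, params.grid_size)
    gy = np.linspace(y0, y1, params.grid_size)
    X, Y = np.meshgrid(gx, gy)
    width2 = (params.sigma / p_cell) ** 2
    d2 = (
        (X[:, :, None] - coords_2d[None, None, :, 0]) ** 2
        + (Y[:, :, None] - coords_2d[None, None, :, 1]) ** 2
    )
    f = (-np.exp(-d2 / width2[None, None, :])).mean(axis=2)
    c0, cx, cy = fit_linear_trend(coords_2d, V_hat[labels])
    g = c0 + cx * X + cy * Y
    V = params.a * f + params.b * g
    if params.cap is not None:
        V = np.where(V > params.cap, np.nan, V)
    return gx, gy, V


def evaluate_correlation(pseudotime: np.ndarray, true_time: np.ndarray) -> float:
    """Pearson correlation between pseudo-time and true-time labels."""
    pseudotime = np.asarray(pseudotime, dtype=float)
    true_time = np.asarray(true_time, dtype=float)
    if len(pseudotime) != len(true_time):
        raise ValueError("length mismatch")
    if len(pseudotime) < 3:
        raise ValueError("need at least 3 cells")
    if pseudotime.std() == 0 or true_time.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    return float(stats.pearsonr(pseudotime, true_time).statistic)


def wilcoxon_stage_test(pseudotime_early: np.ndarray,
                        pseudotime_late: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum p-value for the alternative that the
    early-stage group has stochastically smaller pseudo-time than the
    late-stage group.

    Exact enumeration for small untied samples, normal approximation
    with continuity correction otherwise (scipy's Mann-Whitney U, which
    is equivalent to the rank-sum test).
    """
    early = np.asarray(pseudotime_early, dtype=float)
    late = np.asarray(pseudotime_late, dtype=float)
    if len(early) == 0 or len(late) == 0:
        raise ValueError("both stage groups must be nonempty")
    res = stats.mannwhitneyu(early, late, alternative="less", method="auto")
    return float(res.pvalue)
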