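"""End-to-end pipeline: expression matrix -> differentiation landscape.

Chains the module steps in the canonical order — PCA embedding,
diffusion kernel and cell-level Markov chain, k-means coarse-graining,
KDE boundary-derivative net-flow, pseudo-inverse potential solve,
pseudo-time and directed paths — and bundles every intermediate plus a
run report (bandwidth used, potential-equation residual, steady-state
conservation defect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coarse_grain import ClusterModel, build_cluster_model
from .diffusion_map import DiffusionModel, build_diffusion_model, median_bandwidth
from .landscape import (
    LandscapeResult,
    assign_pseudotime,
    build_paths,
    potential_residual,
    solve_potential,
)
from .netflow import NetFlowEstimate, cluster_netflow
from .preprocess import Embedding, ExpressionMatrix, reduce_dimensions

__all__ = ["LDDResult", "run_ldd", "run_ldd_on_embedding"]


@dataclass
class LDDResult:
    """All artifacts of one landscape run."""

    embedding: Embedding
    diffusion: DiffusionModel
    clusters: ClusterModel
    netflow: NetFlowEstimate
    landscape: LandscapeResult
    report: dict

    @property
    def pseudotime(self) -> np.ndarray:
        return self.landscape.pseudotime

    @property
    def V_hat(self) -> np.ndarray:
        return self.landscape.V_hat


def run_ldd_on_embedding(
    E: Embedding,
    n_clusters: int,
    *,
    epsilon: float | None = None,
    alpha: float = 0.5,
    knn_k: int | None = None,
    symmetrization: str = "or",
    D: float = 1.0,
    pad_bandwidth: bool = False,
    threshold: float | None = None,
    labels: np.ndarray | None = None,
    seed: int = 0,
) -> LDDResult:
    """Run every step downstream of dimension reduction."""
    dm = build_diffusion_model(
        E, epsilon=epsilon, alpha=alpha, knn_k=knn_k, symmetrization=symmetrization
    )
    cm = build_cluster_model(E, dm.P, dm.mu, dm.epsilon, n_clusters, seed, labels=labels)
    nf = cluster_netflow(E, cm.labels, D=D, pad_bandwidth=pad_bandwidth)
    V_hat = solve_potential(cm.P_hat, nf.R_tilde, dm.epsilon)
    pt = assign_pseudotime(V_hat, cm.labels)
    edges, root = build_paths(cm.P_tilde, V_hat, threshold, cm.n_s)
    off = cm.P_tilde - np.diag(np.diag(cm.P_tilde))
    thr = threshold if threshold is not None else (0.01 * off.max() if off.max() > 0 else 0.0)
    ls = LandscapeResult(
        V_hat=V_hat,
        pseudotime=pt,
        edges=edges,
        threshold=float(thr),
        root_cluster=root,
        residual=potential_residual(cm.P_hat, nf.R_tilde, dm.epsilon, V_hat),
    )
    report = {
        "n_cells": E.n_cells,
        "m": E.m,
        "n_clusters": cm.K,
        "epsilon": float(dm.epsilon),
        "alpha": float(dm.alpha),
        "knn_k": int(dm.knn_k),
        "D": float(D),
        "edge_threshold": float(thr),
        "potential_residual": float(ls.residual),
        "conservation_defect": float(abs(cm.n_s @ nf.R_tilde)),
        "root_cluster": int(root),
        "seed": int(seed),
    }
    return LDDResult(E, dm, cm, nf, ls, report)


def run_ldd(
    X: ExpressionMatrix,
    n_clusters: int,
    *,
    m: int = 2,
    seed: int = 0,
    **kwargs,
) -> LDDResult:
    """Full pipeline from a cells x genes expression matrix.

    ``m`` is the PCA dimension (2 by default, matching the scale of the
    bundled benchmarks); remaining keyword arguments are forwarded to
    :func:`run_ldd_on_embedding`.
    """
    E = reduce_dimensions(X, m=m, seed=seed)
    return run_ldd_on_embedding(E, n_clusters, seed=seed, **kwargs)
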