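"""Synthetic benchmarks with births, deaths, drift and diffusion.

The downstream method assumes cells at a *non-equilibrium steady state*:
cells are continuously born in a source region, drift down a potential
(or follow gene-regulatory kinetics), diffuse, and are removed in sink
regions, while the population distribution stays stationary.  This
module simulates exactly that process and returns labelled snapshots
(expression, true age since birth, terminal lineage, coarse stage) so
the whole pipeline can be validated against ground truth.

Three generators are provided:

* a drift-diffusion process in 50 dimensions whose first two coordinates
  feel a "tuning-fork" potential — a single channel that splits into two
  wells — with one birth source at the channel entrance and a death sink
  at each well bottom (two lineages);
* a two-gene mutually-inhibitory toggle switch (two lineages);
* a six-gene network of three coupled toggles producing four terminal
  branches, each with exactly two highly expressed genes.

All simulators share one Euler–Maruyama birth-death engine:
``x(t+dt) = x(t) + drift(x)*dt + sqrt(D*dt)*xi`` with per-step Poisson
births placed uniformly in the source ball and per-step Bernoulli
removal of cells inside any sink ball.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq, fsolve

from .preprocess import ExpressionMatrix, save_expression

logger = logging.getLogger(__name__)

__all__ = [
    "SourceRegion",
    "SinkRegion",
    "TuningForkPotential",
    "DriftDiffusionSpec",
    "GeneNetworkSpec",
    "LabeledDataset",
    "drift_diffusion_spec",
    "toggle_switch_spec",
    "six_gene_spec",
    "simulate_drift_diffusion",
    "simulate_gene_network",
    "write_dataset",
]


class SimulationError(RuntimeError):
    """Raised when a birth-death simulation cannot reach a valid snapshot."""


# --------------------------------------------------------------------------
# regions and specs
# --------------------------------------------------------------------------


@dataclass
class SourceRegion:
    """Ball in which new cells appear.

    ``center`` lives in the first ``len(center)`` coordinates of state
    space (the potential plane for the drift-diffusion model, the full
    gene space for networks).  ``birth_rate`` is births per unit time;
    ``None`` means the engine calibrates it so the long-run population
    matches the spec's target (see the engine docstring).
    """

    center: np.ndarray
    radius: float
    birth_rate: float | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class SinkRegion:
    """Ball in which cells are removed with probability ``removal_prob``
    per time step (a per-step Bernoulli death)."""

    center: np.ndarray
    radius: float
    removal_prob: float
    label: str

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not 0.0 < self.removal_prob <= 1.0:
            raise ValueError("removal_prob must be in (0, 1]")


@dataclass
class TuningForkPotential:
    """Bifurcating potential on the plane: a tilted single-well channel
    that smoothly switches into a double well along the second axis.

    F(x, y) = -tilt*x + walls(x)
              + (1-s(x)) * channel_stiffness/2 * y^2
              + s(x) * barrier_height * (y^2 - y*^2)^2 / y*^4

    where ``s`` is a logistic switch centred at ``switch_x`` with width
    ``switch_width`` and ``y* = branch_halfwidth``.  Quadratic walls
    confine x to [0, channel_length] (soft, stiffness ``wall_stiffness``).
    The gradient includes the cross term from s'(x), so -grad F is an
    exact gradient flow.
    """

    tilt: float = 1.0
    channel_length: float = 4.0
    switch_x: float = 1.5
    switch_width: float = 0.4
    channel_stiffness: float = 2.0
    branch_halfwidth: float = 1.5
    barrier_height: float = 1.0
    wall_stiffness: float = 4.0

    def _switch(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = (x - self.switch_x) / self.switch_width
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -50, 50)))
        return s, s * (1.0 - s) / self.switch_width

    def value(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x, y = xy[:, 0], xy[:, 1]
        s, _ = self._switch(x)
        ys2 = self.branch_halfwidth**2
        u_in = 0.5 * self.channel_stiffness * y**2
        u_out = self.barrier_height * (y**2 - ys2) ** 2 / ys2**2
        walls = 0.5 * self.wall_stiffness * (
            np.minimum(x, 0.0) ** 2 + np.maximum(x - self.channel_length, 0.0) ** 2
        )
        return -self.tilt * x + walls + (1.0 - s) * u_in + s * u_out

    def grad(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x, y = xy[:, 0], xy[:, 1]
        s, sp = self._switch(x)
        ys2 = self.branch_halfwidth**2
        u_in = 0.5 * self.channel_stiffness * y**2
        u_out = self.barrier_height * (y**2 - ys2) ** 2 / ys2**2
        du_in = self.channel_stiffness * y
        du_out = 4.0 * self.barrier_height * y * (y**2 - ys2) / ys2**2
        gx = (
            -self.tilt
            + self.wall_stiffness
            * (np.minimum(x, 0.0) + np.maximum(x - self.channel_length, 0.0))
            + sp * (u_out - u_in)
        )
        gy = (1.0 - s) * du_in + s * du_out
        return np.stack([gx, gy], axis=1)

    def sink_x(self) -> float:
        """x-coordinate where the tilt balances the end wall."""
        return self.channel_length + self.tilt / self.wall_stiffness


def _validate_common(spec) -> None:
    if spec.dt <= 0:
        raise ValueError("dt must be positive")
    if spec.D < 0:
        raise ValueError("noise amplitude D must be >= 0")
    if spec.n_snapshot_cells < 2:
        raise ValueError("n_snapshot_cells must be >= 2")
    if not spec.sink_regions:
        raise ValueError("at least one sink region required")
    centers = [tuple(s.center) for s in spec.sink_regions]
    if len(set(centers)) != len(centers):
        raise ValueError("sink regions must have distinct centers")


@dataclass
class DriftDiffusionSpec:
    """Parameters of the 50-dimensional drift-diffusion benchmark.

    The potential acts on the first two coordinates; the remaining
    ``n_dims - 2`` coordinates carry pure diffusion noise (no drift) and
    start at zero at birth.
    """

    n_dims: int = 50
    dt: float = 0.01
    D: float = 0.02
    potential: TuningForkPotential = field(default_factory=TuningForkPotential)
    source_region: SourceRegion = None  # type: ignore[assignment]
    sink_regions: list[SinkRegion] = None  # type: ignore[assignment]
    target_population: int = 800
    n_snapshot_cells: int = 400
    seed: int = 0
    t_calibrate: float = 18.0
    t_equilibrate: float = 18.0
    initial_cells: int = 0  # cells seeded in the source ball at t=0

    def __post_init__(self) -> None:
        if self.source_region is None:
            self.source_region = SourceRegion(center=[0.3, 0.0], radius=0.3)
        if self.sink_regions is None:
            xs = self.potential.sink_x()
            ys = self.potential.branch_halfwidth
            self.sink_regions = [
                SinkRegion([xs, ys], 0.6, 0.5, "branch_pos"),
                SinkRegion([xs, -ys], 0.6, 0.5, "branch_neg"),
            ]
        if self.n_dims < 2:
            raise ValueError("n_dims must be >= 2")
        _validate_common(self)

    def drift(self, X: np.ndarray) -> np.ndarray:
        V = np.zeros_like(X)
        V[:, :2] = -self.potential.grad(X[:, :2])
        return V


@dataclass
class GeneNetworkSpec:
    """Parameters of a Hill-kinetics gene regulatory network benchmark.

    ``interaction_matrix[i, j]`` is +1 if gene j activates gene i, -1 if
    it inhibits it, 0 otherwise.  The drift of gene i is

        production[i] * prod_act * prod_inh - degradation[i] * x_i

    with ``prod_act = prod_j x_j^n / (K^n + x_j^n)`` over activators and
    ``prod_inh = prod_j K^n / (K^n + x_j^n)`` over inhibitors.  States
    pushed below zero by noise are clipped to zero (events counted).
    """

    n_genes: int
    interaction_matrix: np.ndarray
    production: np.ndarray
    degradation: np.ndarray
    hill_K: float = 1.0
    hill_n: float = 6.0
    hill_K_act: float | None = None  # activation threshold; defaults to hill_K
    D: float = 0.05
    dt: float = 0.01
    source_region: SourceRegion = None  # type: ignore[assignment]
    sink_regions: list[SinkRegion] = None  # type: ignore[assignment]
    target_population: int = 800
    n_snapshot_cells: int = 400
    seed: int = 0
    t_calibrate: float = 30.0
    t_equilibrate: float = 30.0
    initial_cells: int = 0  # cells seeded in the source ball at t=0

    def __post_init__(self) -> None:
        self.interaction_matrix = np.asarray(self.interaction_matrix, dtype=int)
        self.production = np.asarray(self.production, dtype=float)
        self.degradation = np.asarray(self.degradation, dtype=float)
        if self.n_genes not in (2, 6):
            raise ValueError("n_genes must be 2 or 6")
        if self.interaction_matrix.shape != (self.n_genes, self.n_genes):
            raise ValueError("interaction_matrix must be n_genes x n_genes")
        if self.source_region is None or self.sink_regions is None:
            raise ValueError("source_region and sink_regions are required")
        if self.n_genes == 2:
            if not (
                self.interaction_matrix[0, 1] == -1
                and self.interaction_matrix[1, 0] == -1
            ):
                raise ValueError("two-gene network must be mutually inhibitory")
        _validate_common(self)

    def drift(self, X: np.ndarray) -> np.ndarray:
        Kn = self.hill_K**self.hill_n
        Ka = (self.hill_K_act if self.hill_K_act is not None else self.hill_K) ** self.hill_n
        Xn = np.maximum(X, 0.0) ** self.hill_n
        act = Xn / (Ka + Xn)
        inh = Kn / (Kn + Xn)
        prod = np.tile(self.production, (X.shape[0], 1))
        for i in range(self.n_genes):
            for j in range(self.n_genes):
                if self.interaction_matrix[i, j] == 1:
                    prod[:, i] *= act[:, j]
                elif self.interaction_matrix[i, j] == -1:
                    prod[:, i] *= inh[:, j]
        return prod - self.degradation * X


@dataclass
class LabeledDataset:
    """Snapshot of a birth-death simulation with ground-truth labels.

    ``true_time`` is each cell's age since birth; ``lineage`` the label
    of the sink basin its noise-free flow reaches; ``stage`` a coarse
    early/mid/late label from age terciles.  ``meta`` records engine
    diagnostics (birth rate used, mean population, clip count).
    """

    expression: ExpressionMatrix
    true_time: np.ndarray
    lineage: list[str]
    stage: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.true_time = np.asarray(self.true_time, dtype=float)
        n = self.expression.n_cells
        if len(self.true_time) != n or len(self.lineage) != n:
            raise ValueError("label lengths do not match cell count")
        if (self.true_time < 0).any():
            raise ValueError("true_time must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.expression.n_cells


# --------------------------------------------------------------------------
# default spec factories
# --------------------------------------------------------------------------


def drift_diffusion_spec(seed: int = 0, **overrides) -> DriftDiffusionSpec:
    """The 50-dimensional bifurcating drift-diffusion benchmark."""
    return DriftDiffusionSpec(seed=seed, **overrides)


def _toggle_fixed_points(a: float, K: float, n: float):
    """(high, low) and symmetric fixed points of the 2-gene toggle with
    unit degradation: x_i' = a K^n/(K^n + x_j^n) - x_i."""
    Kn = K**n

    def inh(x):
        return Kn / (Kn + x**n)

    sym = brentq(lambda x: a * inh(x) - x, 1e-9, a + 1.0)
    hi, lo = fsolve(
        lambda v: [a * inh(v[1]) - v[0], a * inh(v[0]) - v[1]],
        [a * 0.98, a * inh(a * 0.98)],
        full_output=False,
    )
    if abs(hi - lo) < 1e-6:
        raise ValueError("toggle parameters are not bistable")
    return float(max(hi, lo)), float(min(hi, lo)), float(sym)


def toggle_switch_spec(seed: int = 0, **overrides) -> GeneNetworkSpec:
    """Two-gene mutually-inhibitory toggle: births near the undecided
    symmetric saddle, deaths at the two committed attractors.

    Strong production (a/K = 20) and a steep Hill curve make lineage
    commitment fast relative to the post-commitment journey, so a
    cell's position is an informative clock for its age — the regime in
    which cluster-level pseudo-time can track true time.
    """
    a, K, n = 20.0, 1.0, 6.0
    hi, lo, sym = _toggle_fixed_points(a, K, n)
    defaults = dict(
        n_genes=2,
        interaction_matrix=[[0, -1], [-1, 0]],
        production=[a, a],
        degradation=[1.0, 1.0],
        hill_K=K,
        hill_n=n,
        D=0.05,
        source_region=SourceRegion(center=[sym, sym], radius=0.1),
        sink_regions=[
            SinkRegion([hi, lo], 3.0, 0.3, "g1_high"),
            SinkRegion([lo, hi], 3.0, 0.3, "g2_high"),
        ],
        seed=seed,
    )
    defaults.update(overrides)
    return GeneNetworkSpec(**defaults)


def six_gene_spec(seed: int = 0, **overrides) -> GeneNetworkSpec:
    """Six-gene network: a primary toggle (g1, g2) gates two secondary
    toggles (g3, g4) and (g5, g6), yielding four terminal branches with
    exactly two high genes each ({g1,g3}, {g1,g4}, {g2,g5}, {g2,g6}).

    The activation threshold sits midway up the primary journey, so a
    secondary toggle only switches on once its parent gene has committed
    and risen — two sequential bifurcations, four lineages.
    """
    a, K, n = 20.0, 1.0, 6.0
    K_act = 5.0
    hi, lo, sym = _toggle_fixed_points(a, K, n)
    Kan = K_act**n

    def act(x):
        return x**n / (Kan + x**n)

    def inh(x):
        return (K**n) / (K**n + x**n)

    # secondary toggle under a committed parent: production a*act(hi)
    hi2, lo2, _ = _toggle_fixed_points(a * act(hi), K, n)
    # secondary genes of the losing branch settle near zero
    off = float(fsolve(lambda v: a * act(lo) * inh(v) - v, 0.01)[0])
    # undecided secondary level while the parent is still at the saddle
    sym2 = brentq(lambda x: a * act(sym) * inh(x) - x, 0.0, a + 1.0)

    # interaction_matrix[i, j]: effect of gene j on gene i
    M = np.zeros((6, 6), dtype=int)
    M[0, 1] = M[1, 0] = -1  # primary toggle
    M[2, 3] = M[3, 2] = -1  # secondary toggle A
    M[4, 5] = M[5, 4] = -1  # secondary toggle B
    M[2, 0] = M[3, 0] = 1  # g1 activates A
    M[4, 1] = M[5, 1] = 1  # g2 activates B

    def terminal(primary_high: int, secondary_high: int) -> np.ndarray:
        v = np.full(6, off)
        v[primary_high], v[1 - primary_high] = hi, lo
        pair = (2, 3) if primary_high == 0 else (4, 5)
        v[pair[0]], v[pair[1]] = (
            (hi2, lo2) if secondary_high == 0 else (lo2, hi2)
        )
        return v

    defaults = dict(
        n_genes=6,
        interaction_matrix=M,
        production=[a] * 6,
        degradation=[1.0] * 6,
        hill_K=K,
        hill_n=n,
        hill_K_act=K_act,
        D=0.05,
        source_region=SourceRegion(
            center=[sym, sym, sym2, sym2, sym2, sym2], radius=0.1
        ),
        sink_regions=[
            SinkRegion(terminal(0, 0), 3.0, 0.3, "g1_g3"),
            SinkRegion(terminal(0, 1), 3.0, 0.3, "g1_g4"),
            SinkRegion(terminal(1, 0), 3.0, 0.3, "g2_g5"),
            SinkRegion(terminal(1, 1), 3.0, 0.3, "g2_g6"),
        ],
        t_calibrate=30.0,
        t_equilibrate=30.0,
        seed=seed,
    )
    defaults.update(overrides)
    return GeneNetworkSpec(**defaults)


# --------------------------------------------------------------------------
# the birth-death engine
# --------------------------------------------------------------------------


def _sample_ball(rng: np.random.Generator, center: np.ndarray, radius: float, n: int) -> np.ndarray:
    """Uniform samples in a d-ball."""
    d = len(center)
    z = rng.standard_normal((n, d))
    z /= np.maximum(np.linalg.norm(z, axis=1, keepdims=True), 1e-300)
    r = radius * rng.random(n) ** (1.0 / d)
    return center + z * r[:, None]


def _births(rng, spec, n_new: int) -> np.ndarray:
    d_region = len(spec.source_region.center)
    pts = np.zeros((n_new, _state_dim(spec)))
    pts[:, :d_region] = _sample_ball(
        rng, spec.source_region.center, spec.source_region.radius, n_new
    )
    return pts


def _state_dim(spec) -> int:
    return spec.n_dims if hasattr(spec, "n_dims") and not hasattr(spec, "n_genes") else spec.n_genes


def _run_birth_death(spec, clip_negative: bool):
    """Simulate the birth-death process to an approximately stationary
    population and return (positions, ages, meta).

    Two phases: a calibration burn-in with a provisional birth rate
    during which the mean lifetime of dying cells is measured, then an
    equilibration phase with the rate fixed at
    ``target_population / mean_lifetime`` so births balance deaths near
    the target population.  A user-supplied ``birth_rate`` skips the
    recalibration and is used throughout.
    """
    rng = np.random.default_rng(spec.seed)
    dim = _state_dim(spec)
    sqrt_noise = math.sqrt(spec.D * spec.dt)
    user_rate = spec.source_region.birth_rate
    rate = user_rate if user_rate is not None else spec.target_population / 5.0

    n0 = getattr(spec, "initial_cells", 0)
    if n0:
        pos = _births(rng, spec, n0)
        if clip_negative:
            pos = np.maximum(pos, 0.0)
    else:
        pos = np.zeros((0, dim))
    age = np.zeros(len(pos))
    n_clip = 0
    lifetimes: list[float] = []
    pop_trace: list[int] = []
    max_pop = max(20 * spec.target_population, 5000)

    def describe_rates() -> str:
        sinks = ", ".join(
            f"{s.label}: p={s.removal_prob}/step" for s in spec.sink_regions
        )
        return f"birth_rate={rate:.3g}/time, sinks [{sinks}]"

    def step(collect_lifetimes: bool, collect_pop: bool):
        nonlocal pos, age, n_clip
        if len(pos):
            pos = pos + spec.drift(pos) * spec.dt
            if spec.D > 0:
                pos = pos + sqrt_noise * rng.standard_normal(pos.shape)
            if clip_negative:
                neg = pos < 0
                n_clip += int(neg.sum())
                pos[neg] = 0.0
            if not np.isfinite(pos).all():
                raise SimulationError(
                    "non-finite coordinates during simulation; reduce dt or D"
                )
            age = age + spec.dt
            # deaths
            dead = np.zeros(len(pos), dtype=bool)
            for sink in spec.sink_regions:
                d_region = len(sink.center)
                inside = (
                    np.linalg.norm(pos[:, :d_region] - sink.center, axis=1)
                    <= sink.radius
                )
                hit = inside & (rng.random(len(pos)) < sink.removal_prob)
                dead |= hit
            if dead.any():
                if collect_lifetimes:
                    lifetimes.extend(age[dead].tolist())
                pos = pos[~dead]
                age = age[~dead]
        # births
        n_new = rng.poisson(rate * spec.dt)
        if n_new:
            newborn = _births(rng, spec, n_new)
            if clip_negative:
                newborn = np.maximum(newborn, 0.0)
            pos = np.vstack([pos, newborn])
            age = np.concatenate([age, np.zeros(n_new)])
        if len(pos) > max_pop:
            raise SimulationError(
                f"population exploded past {max_pop} cells; unbalanced rates ({describe_rates()})"
            )
        if collect_pop:
            pop_trace.append(len(pos))

    n1 = int(round(spec.t_calibrate / spec.dt))
    for i in range(n1):
        step(collect_lifetimes=i >= n1 // 2, collect_pop=False)

    if user_rate is None:
        if not lifetimes:
            raise SimulationError(
                "no deaths observed during calibration; unbalanced rates "
                f"({describe_rates()}) — sinks may be unreachable"
            )
        mean_life = float(np.mean(lifetimes))
        rate = spec.target_population / mean_life
    n2 = int(round(spec.t_equilibrate / spec.dt))
    for i in range(n2):
        step(collect_lifetimes=False, collect_pop=i >= n2 // 2)

    if len(pos) == 0:
        raise SimulationError(
            f"population extinct before snapshot; unbalanced rates ({describe_rates()})"
        )
    meta = {
        "birth_rate": float(rate),
        "mean_population": float(np.mean(pop_trace)) if pop_trace else float(len(pos)),
        "final_population": int(len(pos)),
        "n_negative_clips": int(n_clip),
        "mean_lifetime": float(np.mean(lifetimes)) if lifetimes else float("nan"),
    }
    return pos, age, meta


def _flow_lineage(points: np.ndarray, drift: Callable, sinks: list[SinkRegion],
                  dt: float, max_steps: int = 20000) -> list[str]:
    """Deterministic (noise-free) flow map: integrate each point's drift
    until it enters a sink ball; points still undecided after
    ``max_steps`` (e.g. exactly on a separatrix) get the nearest sink."""
    d_region = len(sinks[0].center)
    x = points[:, :d_region].copy()
    labels = np.full(len(x), -1, dtype=int)
    active = np.ones(len(x), dtype=bool)
    centers = np.array([s.center for s in sinks])
    radii = np.array([s.radius for s in sinks])
    for _ in range(max_steps):
        if not active.any():
            break
        xa = x[active]
        dist = np.linalg.norm(xa[:, None, :] - centers[None, :, :], axis=2)
        hit = dist <= radii[None, :]
        any_hit = hit.any(axis=1)
        if any_hit.any():
            idx = np.flatnonzero(active)[any_hit]
            labels[idx] = np.argmax(hit[any_hit], axis=1)
            active[idx] = False
            if not active.any():
                break
            xa = x[active]
        full = np.zeros((len(xa), points.shape[1]))
        full[:, :d_region] = xa
        x[active] = xa + drift(full)[:, :d_region] * dt
    if active.any():
        xa = x[active]
        dist = np.linalg.norm(xa[:, None, :] - centers[None, :, :], axis=2)
        labels[active] = np.argmin(dist, axis=1)
    return [sinks[i].label for i in labels]


def _stage_labels(true_time: np.ndarray) -> list[str]:
    q1, q2 = np.quantile(true_time, [1 / 3, 2 / 3])
    return [
        "early" if t <= q1 else ("mid" if t <= q2 else "late") for t in true_time
    ]


def _snapshot(spec, pos, age, meta, feature_prefix: str, clip_negative: bool) -> LabeledDataset:
    rng = np.random.default_rng(spec.seed + 1_000_003)
    n = spec.n_snapshot_cells
    if len(pos) < n:
        raise SimulationError(
            f"population ({len(pos)} cells) smaller than requested snapshot "
            f"({n}); raise target_population or birth rate"
        )
    keep = np.sort(rng.choice(len(pos), size=n, replace=False))
    pos, age = pos[keep], age[keep]
    lineage = _flow_lineage(pos, spec.drift, spec.sink_regions, spec.dt)
    dim = pos.shape[1]
    expr = ExpressionMatrix(
        pos,
        [f"cell_{i:04d}" for i in range(n)],
        [f"{feature_prefix}{j + 1}" for j in range(dim)],
    )
    return LabeledDataset(expr, age, lineage, _stage_labels(age), meta)


def simulate_drift_diffusion(spec: DriftDiffusionSpec) -> LabeledDataset:
    """Run the drift-diffusion birth-death process and return a labelled
    stationary snapshot of ``spec.n_snapshot_cells`` cells."""
    pos, age, meta = _run_birth_death(spec, clip_negative=False)
    return _snapshot(spec, pos, age, meta, "dim", clip_negative=False)


def simulate_gene_network(spec: GeneNetworkSpec) -> LabeledDataset:
    """Run a gene-network birth-death process and return a labelled
    stationary snapshot.  Negative-expression clip events are counted in
    ``dataset.meta['n_negative_clips']`` and logged."""
    pos, age, meta = _run_birth_death(spec, clip_negative=True)
    if meta["n_negative_clips"]:
        logger.info(
            "clipped %d negative expression events to zero", meta["n_negative_clips"]
        )
    return _snapshot(spec, pos, age, meta, "g", clip_negative=True)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def write_dataset(dataset: LabeledDataset, outdir: str | Path, format: str = "csv") -> dict[str, Path]:
    """Write expression (+ sidecars for mtx) and a labels TSV with
    columns cell_id, true_time, lineage, stage.  Round-trips through
    :func:`ldd.preprocess.load_expression`."""
    if format not in ("csv", "mtx"):
        raise ValueError("format must be 'csv' or 'mtx'")
    if dataset.n_cells == 0:
        raise ValueError("refusing to write an empty dataset (0 cells)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr_path = outdir / ("expression.csv" if format == "csv" else "expression.mtx")
    save_expression(dataset.expression, expr_path, format=format)
    labels = pd.DataFrame(
        {
            "cell_id": dataset.expression.cell_ids,
            "true_time": dataset.true_time,
            "lineage": dataset.lineage,
            "stage": dataset.stage if dataset.stage is not None else [""] * dataset.n_cells,
        }
    )
    labels_path = outdir / "labels.tsv"
    labels.to_csv(labels_path, sep="\t", index=False)
    return {"expression": expr_path, "labels": labels_path}
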