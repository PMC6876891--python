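"""Canonical benchmark configurations used by the validation suite.

Each benchmark pairs a synthetic birth-death generator with the cluster
count appropriate to its topology: 4 clusters for the two-lineage
drift-diffusion process (stem, bifurcation, two branches), 7 for the
two-gene toggle, 9 for the hierarchical six-gene network (stem, primary
bifurcation, two mid-branches, two secondary bifurcations — merged into
the mid-branch segments — and four terminal branches).
"""

from __future__ import annotations

from .landscape import evaluate_correlation
from .pipeline import LDDResult, run_ldd
from .synthetic import (
    LabeledDataset,
    drift_diffusion_spec,
    simulate_drift_diffusion,
    simulate_gene_network,
    six_gene_spec,
    toggle_switch_spec,
)

__all__ = ["BENCHMARKS", "run_benchmark", "benchmark_correlation"]

BENCHMARKS = {
    "driftdiff": (drift_diffusion_spec, simulate_drift_diffusion, 4),
    "toggle2": (toggle_switch_spec, simulate_gene_network, 7),
    "net6": (six_gene_spec, simulate_gene_network, 9),
}


def run_benchmark(model: str, seed: int) -> tuple[LabeledDataset, LDDResult]:
    """Simulate benchmark ``model`` and run the full pipeline on it."""
    factory, simulate, n_clusters = BENCHMARKS[model]
    ds = simulate(factory(seed=seed))
    res = run_ldd(ds.expression, n_clusters=n_clusters, seed=seed)
    return ds, res


def benchmark_correlation(model: str, seed: int) -> float:
    """Pearson correlation between pipeline pseudo-time and the
    simulator's true cell ages for one benchmark replicate."""
    ds, res = run_benchmark(model, seed)
    return evaluate_correlation(res.pseudotime, ds.true_time)
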