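"""Shared fixtures: one simulated dataset per benchmark, run once."""

import numpy as np
import pytest

from ldd import (
    drift_diffusion_spec,
    run_ldd,
    simulate_drift_diffusion,
    simulate_gene_network,
    six_gene_spec,
    toggle_switch_spec,
)


@pytest.fixture(scope="session")
def drift_data():
    return simulate_drift_diffusion(drift_diffusion_spec(seed=1))


@pytest.fixture(scope="session")
def drift_result(drift_data):
    return run_ldd(drift_data.expression, n_clusters=4, seed=1)


@pytest.fixture(scope="session")
def toggle_data():
    return simulate_gene_network(toggle_switch_spec(seed=1))


@pytest.fixture(scope="session")
def toggle_result(toggle_data):
    return run_ldd(toggle_data.expression, n_clusters=7, seed=1)


@pytest.fixture(scope="session")
def sixgene_data():
    return simulate_gene_network(six_gene_spec(seed=1))


@pytest.fixture(scope="session")
def sixgene_result(sixgene_data):
    return run_ldd(sixgene_data.expression, n_clusters=9, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
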