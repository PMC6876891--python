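import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import ks_2samp

import ldd.synthetic as syn
from ldd.preprocess import load_expression


def small_drift_spec(seed=0, **kw):
    """Scaled-down drift-diffusion process for fast tests."""
    defaults = dict(
        n_dims=10,
        target_population=150,
        n_snapshot_cells=60,
        t_calibrate=12.0,
        t_equilibrate=10.0,
        seed=seed,
    )
    defaults.update(kw)
    return syn.drift_diffusion_spec(**defaults)


class TestDriftDiffusion:
    def test_snapshot_has_requested_cells(self, drift_data):
        assert drift_data.n_cells == 400
        assert drift_data.expression.values.shape == (400, 50)

    def test_true_time_nonnegative_and_lineages_from_sinks(self, drift_data):
        assert (drift_data.true_time >= 0).all()
        assert set(drift_data.lineage) == {"branch_pos", "branch_neg"}

    def test_static_when_no_forces(self):
        """With D=0, F=0 and no birth/death activity the population
        stays exactly where it was seeded."""
        pot = syn.TuningForkPotential(
            tilt=0.0, channel_stiffness=0.0, barrier_height=0.0, wall_stiffness=0.0
        )
        common = dict(
            n_dims=4,
            D=0.0,
            potential=pot,
            source_region=syn.SourceRegion([0.0, 0.0], 1.0, birth_rate=0.0),
            sink_regions=[syn.SinkRegion([500.0, 0.0], 0.1, 1.0, "far")],
            initial_cells=50,
            n_snapshot_cells=50,
            seed=11,
        )
        short = syn.simulate_drift_diffusion(
            syn.DriftDiffusionSpec(t_calibrate=0.5, t_equilibrate=0.5, **common)
        )
        long = syn.simulate_drift_diffusion(
            syn.DriftDiffusionSpec(t_calibrate=0.5, t_equilibrate=5.0, **common)
        )
        np.testing.assert_array_equal(
            short.expression.values, long.expression.values
        )

    def test_balanced_rates_hold_population_near_target(self):
        """Calibrated birth rate balances sink deaths: long-run mean
        population within 10% of target, Monte-Carlo over 20 seeds."""
        means = []
        for seed in range(20):
            ds = syn.simulate_drift_diffusion(small_drift_spec(seed=seed))
            means.append(ds.meta["mean_population"])
        assert abs(np.mean(means) / 150.0 - 1.0) < 0.1

    def test_late_snapshots_share_distribution(self):
        """Stationarity: snapshots of the same chain at two late times
        have small KS distance on the channel coordinate."""
        a = syn.simulate_drift_diffusion(small_drift_spec(seed=3, t_equilibrate=10.0))
        b = syn.simulate_drift_diffusion(small_drift_spec(seed=3, t_equilibrate=16.0))
        stat = ks_2samp(a.expression.values[:, 0], b.expression.values[:, 0]).statistic
        assert stat < 0.25

    def test_noise_dimension_relabelling_is_immaterial(self, drift_data, rng):
        """Dims beyond the first two are exchangeable pure noise:
        permuting them leaves every pairwise distance unchanged."""
        X = drift_data.expression.values
        perm = np.concatenate([[0, 1], 2 + rng.permutation(X.shape[1] - 2)])
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(X), pdist(X[:, perm]), rtol=1e-12)

    def test_extinction_reported_with_rates(self):
        spec = small_drift_spec(seed=0)
        spec.source_region.birth_rate = 0.0
        with pytest.raises(syn.SimulationError, match="birth_rate=0"):
            syn.simulate_drift_diffusion(spec)

    def test_unreachable_sinks_reported(self):
        spec = small_drift_spec(
            seed=0,
            sink_regions=[syn.SinkRegion([500.0, 500.0], 0.1, 0.5, "far")],
            t_calibrate=2.0,
        )
        with pytest.raises(syn.SimulationError, match="unbalanced|unreachable"):
            syn.simulate_drift_diffusion(spec)


class TestGeneNetworks:
    def test_toggle_bistable_fixed_points(self):
        """Noise-free integration from perturbed starts converges to two
        distinct states where production balances degradation."""
        spec = syn.toggle_switch_spec(seed=0)
        sym = spec.source_region.center[0]

        def ode(t, x):
            return spec.drift(x[None, :])[0]

        ends = []
        for start in ([sym + 0.2, sym - 0.2], [sym - 0.2, sym + 0.2]):
            sol = solve_ivp(ode, (0, 80), start, rtol=1e-10, atol=1e-12)
            ends.append(sol.y[:, -1])
        a, b = ends
        assert np.linalg.norm(a - b) > 1.0
        for x in ends:
            np.testing.assert_allclose(ode(0.0, x), 0.0, atol=1e-6)

    def test_terminal_cells_express_one_gene(self, toggle_data):
        """Committed branches: one gene high, the other very low."""
        X = toggle_data.expression.values
        lin = np.array(toggle_data.lineage)
        thr = syn.toggle_switch_spec(seed=0).hill_K  # between hi and lo states
        late = toggle_data.true_time > np.quantile(toggle_data.true_time, 0.8)
        for label, hi_gene, lo_gene in [("g1_high", 0, 1), ("g2_high", 1, 0)]:
            sel = late & (lin == label)
            assert sel.sum() > 0
            assert (X[sel, hi_gene] > thr).mean() > 0.95
            assert (X[sel, lo_gene] < thr).mean() > 0.95

    def test_seeded_reproducibility(self):
        spec_a = syn.toggle_switch_spec(seed=5, n_snapshot_cells=80,
                                        target_population=200)
        spec_b = syn.toggle_switch_spec(seed=5, n_snapshot_cells=80,
                                        target_population=200)
        a = syn.simulate_gene_network(spec_a)
        b = syn.simulate_gene_network(spec_b)
        np.testing.assert_array_equal(a.expression.values, b.expression.values)
        np.testing.assert_array_equal(a.true_time, b.true_time)
        assert a.lineage == b.lineage

    def test_six_gene_terminal_states_have_two_high_genes(self, sixgene_data):
        X = sixgene_data.expression.values
        lin = np.array(sixgene_data.lineage)
        late = sixgene_data.true_time > np.quantile(sixgene_data.true_time, 0.8)
        expected = {
            "g1_g3": (0, 2), "g1_g4": (0, 3), "g2_g5": (1, 4), "g2_g6": (1, 5)
        }
        assert set(lin) == set(expected)
        for label, high in expected.items():
            sel = late & (lin == label)
            if sel.sum() == 0:
                continue
            n_high = (X[sel] > 5.0).sum(axis=1)
            assert np.median(n_high) == 2
            frac_high = (X[sel][:, list(high)] > 5.0).mean()
            assert frac_high > 0.9

    def test_mutual_inhibition_required(self):
        with pytest.raises(ValueError, match="mutually inhibitory"):
            syn.GeneNetworkSpec(
                n_genes=2,
                interaction_matrix=[[0, 1], [1, 0]],
                production=[1.0, 1.0],
                degradation=[1.0, 1.0],
                source_region=syn.SourceRegion([0, 0], 0.1),
                sink_regions=[syn.SinkRegion([1, 0], 0.1, 0.5, "a")],
            )


class TestWriteDataset:
    @pytest.mark.parametrize("fmt", ["csv", "mtx"])
    def test_round_trip(self, tmp_path, fmt):
        ds = syn.simulate_drift_diffusion(small_drift_spec(seed=2))
        paths = syn.write_dataset(ds, tmp_path / fmt, format=fmt)
        back = load_expression(paths["expression"], fmt)
        np.testing.assert_allclose(back.values, ds.expression.values, rtol=1e-8)
        assert back.cell_ids == ds.expression.cell_ids
        labels = (tmp_path / fmt / "labels.tsv").read_text().splitlines()
        assert labels[0].split("\t") == ["cell_id", "true_time", "lineage", "stage"]
        assert len(labels) == ds.n_cells + 1

    def test_bad_format_rejected(self, tmp_path, drift_data):
        with pytest.raises(ValueError):
            syn.write_dataset(drift_data, tmp_path, format="xlsx")
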