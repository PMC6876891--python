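import numpy as np
import pytest
from itertools import combinations

from ldd.landscape import (
    SurfaceSpec,
    assign_pseudotime,
    build_paths,
    evaluate_correlation,
    landscape_surface,
    maximum_weight_tree,
    solve_potential,
    wilcoxon_stage_test,
)


class TestSolvePotential:
    def test_zero_netflow_gives_zero_potential(self):
        P = np.array([[0.6, 0.4], [0.3, 0.7]])
        np.testing.assert_allclose(solve_potential(P, np.zeros(2), 0.5), 0.0)

    def test_two_cluster_closed_form(self):
        """For the symmetric 2-state chain the minimum-norm solution of
        (P - I) V = -R eps with R = (r, -r) is V = (r eps, -r eps)."""
        P = np.array([[0.5, 0.5], [0.5, 0.5]])
        r, eps = 1.7, 0.3
        V = solve_potential(P, np.array([r, -r]), eps)
        np.testing.assert_allclose(V, [r * eps, -r * eps], rtol=1e-12)

    def test_residual_beats_random_perturbations(self, rng):
        K = 5
        M = rng.random((K, K)) + 0.1
        P = M / M.sum(axis=1, keepdims=True)
        R = rng.standard_normal(K)
        eps = 0.4
        V = solve_potential(P, R, eps)
        A = P - np.eye(K)

        def resid(v):
            return np.linalg.norm(A @ v + R * eps)

        base = resid(V)
        for _ in range(1000):
            assert base <= resid(V + rng.standard_normal(K) * 0.1) + 1e-12

    def test_minimum_norm_orthogonal_to_constants(self, rng):
        M = rng.random((4, 4)) + 0.2
        P = M / M.sum(axis=1, keepdims=True)  # irreducible
        V = solve_potential(P, rng.standard_normal(4), 0.2)
        assert abs(V.sum()) < 1e-8 * max(1.0, np.abs(V).max())

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            solve_potential(np.full((2, 2), np.nan), np.zeros(2), 0.1)


class TestPseudotime:
    def test_additive_inverse_of_cluster_potential(self):
        V = np.array([1.0, 0.0])
        labels = np.array([0, 0, 1])
        np.testing.assert_allclose(
            assign_pseudotime(V, labels), [-1.0, -1.0, 0.0]
        )

    def test_shift_gauge(self, rng):
        V = rng.standard_normal(3)
        labels = rng.integers(0, 3, size=20)
        base = assign_pseudotime(V, labels)
        shifted = assign_pseudotime(V + 5.0, labels)
        np.testing.assert_allclose(shifted, base - 5.0, atol=1e-12)

    def test_root_cluster_is_earliest(self, drift_result):
        root = drift_result.landscape.root_cluster
        pt = drift_result.pseudotime
        lab = drift_result.clusters.labels
        assert pt[lab == root].mean() == pytest.approx(pt.min())


class TestPaths:
    def test_zero_threshold_keeps_every_edge(self):
        P_tilde = np.array([[0.2, 0.1, 0.0], [0.1, 0.2, 0.05], [0.0, 0.05, 0.3]])
        V = np.array([2.0, 1.0, 0.0])
        edges, root = build_paths(P_tilde, V, threshold=0.0)
        assert {(a, b) for a, b, _ in edges} == {(0, 1), (1, 2)}
        assert root == 0

    def test_edges_point_downhill(self, drift_result):
        V = drift_result.V_hat
        for a, b, _ in drift_result.landscape.edges:
            assert V[a] >= V[b]

    def test_fixture_tree_matches_simulated_topology(self, drift_data, drift_result):
        """Spanning-tree extraction on the bifurcating fixture: the
        birth-region cluster is the root, the two death-region clusters
        are the leaves (one bifurcation, two lineages)."""
        cm = drift_result.clusters
        edges, root = maximum_weight_tree(cm.P_tilde, drift_result.V_hat)
        assert len(edges) == cm.K - 1
        X = drift_data.expression.values[:, :2]
        lab = cm.labels
        src = lab[np.argmin(np.linalg.norm(X - [0.3, 0.0], axis=1))]
        sinks = {
            lab[np.argmin(np.linalg.norm(X - [4.25, 1.5], axis=1))],
            lab[np.argmin(np.linalg.norm(X - [4.25, -1.5], axis=1))],
        }
        assert root == src
        heads = {a for a, _, _ in edges}
        leaves = set(range(cm.K)) - heads
        assert leaves == sinks


class TestSurface:
    def test_far_field_reduces_to_trend(self, rng):
        coords = rng.standard_normal((20, 2))
        labels = np.zeros(20, dtype=int)
        P_tilde = np.array([[1.0]])
        V = np.array([2.0])
        spec = SurfaceSpec(grid_size=5, sigma=0.1, a=1.0, b=1.0,
                           extent=(100.0, 101.0, 100.0, 101.0))
        gx, gy, Vg = landscape_surface(coords, labels, P_tilde, V, spec)
        # f ~ 0 far away; g is the fitted plane = const 2 here
        np.testing.assert_allclose(Vg, 2.0, atol=1e-10)

    def test_single_sample_well_depth(self):
        coords = np.array([[0.0, 0.0]])
        spec = SurfaceSpec(grid_size=3, sigma=0.5, a=1.0, b=0.0,
                           extent=(-1.0, 1.0, -1.0, 1.0))
        _, _, Vg = landscape_surface(coords, np.array([0]), np.array([[0.7]]),
                                     np.array([1.0]), spec)
        assert Vg[1, 1] == pytest.approx(-1.0)  # grid centre on the sample

    def test_linear_in_mixing_coefficients(self, rng):
        coords = rng.standard_normal((15, 2))
        labels = rng.integers(0, 2, size=15)
        P_tilde = np.array([[0.4, 0.1], [0.1, 0.4]])
        V = np.array([1.0, -1.0])
        _, _, V1 = landscape_surface(coords, labels, P_tilde, V,
                                     SurfaceSpec(grid_size=8, a=1.0, b=0.0))
        _, _, V2 = landscape_surface(coords, labels, P_tilde, V,
                                     SurfaceSpec(grid_size=8, a=2.0, b=0.0))
        np.testing.assert_allclose(V2, 2 * V1, rtol=1e-12)


class TestEvaluation:
    def test_correlation_limits(self):
        x = np.array([0.1, 0.5, 0.9, 1.4])
        assert evaluate_correlation(x, x) == pytest.approx(1.0)
        assert evaluate_correlation(x, -x) == pytest.approx(-1.0)

    def test_correlation_hand_value(self):
        assert evaluate_correlation(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        ) == pytest.approx(0.981980506, abs=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            evaluate_correlation(np.ones(5), np.arange(5.0))

    def test_wilcoxon_exact_small_sample(self):
        """early={1,2}, late={3,4}: only 1 of the C(4,2)=6 rank splits
        is as extreme, so the exact one-sided p-value is 1/6."""
        p = wilcoxon_stage_test(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert p == pytest.approx(1 / 6, rel=1e-12)

    def test_wilcoxon_exact_matches_enumeration(self):
        """Brute-force enumeration of rank assignments reproduces the
        returned p-value for a slightly larger untied sample."""
        early = np.array([1.0, 2.5, 3.0])
        late = np.array([2.0, 4.0, 5.0, 6.0])
        p = wilcoxon_stage_test(early, late)
        pooled = np.concatenate([early, late])
        ranks = pooled.argsort().argsort() + 1
        observed = ranks[: len(early)].sum()
        count = sum(
            1
            for c in combinations(range(len(pooled)), len(early))
            if ranks[list(c)].sum() <= observed
        )
        assert p == pytest.approx(count / 35, rel=1e-12)  # C(7,3)=35

    def test_wilcoxon_wrong_direction_near_one(self):
        p = wilcoxon_stage_test(np.arange(10.0) + 100, np.arange(10.0))
        assert p > 0.99

    def test_wilcoxon_null_calibration(self):
        """Under exchangeable groups the one-sided p is ~uniform: the
        median over 200 simulations sits near 1/2."""
        rng = np.random.default_rng(0)
        ps = [
            wilcoxon_stage_test(rng.standard_normal(30), rng.standard_normal(30))
            for _ in range(200)
        ]
        assert 0.3 < np.median(ps) < 0.7

    def test_wilcoxon_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_stage_test(np.array([]), np.array([1.0]))
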