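"""Entropy solver, stationary distribution and capacities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from volent import (
    WeightedNetwork,
    capacity_tables,
    edge_capacity_matrix,
    edge_transition_matrix,
    node_capacities,
    normalize_volume,
    orient,
    rescale_unnormalized_entropy,
    solve_volume_entropy,
    spectral_radius,
    stationary_distribution,
)
from volent.datasets import TOY_BRIDGES
from conftest import complete_graph, cycle_graph, petersen_graph


class TestEdgeTransitionMatrix:
    def test_toy_graph_is_24_by_24_sparse(self, toy):
        L = edge_transition_matrix(orient(toy), 1.0)
        assert L.shape == (24, 24)
        # each row e has one nonzero per non-backtracking successor
        assert L.nnz < 24 * 24

    def test_h_zero_is_nonbacktracking_adjacency(self, k4_normalized):
        edges = orient(k4_normalized)
        L = edge_transition_matrix(edges, 0.0)
        assert set(np.unique(L.toarray())) == {0.0, 1.0}
        # K4: every oriented edge has exactly d - 1 = 2 continuations
        np.testing.assert_array_equal(L.toarray().sum(axis=1), 2.0)
        # no transition ever backtracks
        dense = L.toarray()
        for e in range(edges.q):
            assert dense[e, edges.reverse(e)] == 0.0

    def test_cycle_rows_have_single_successor(self):
        edges = orient(cycle_graph(4))
        L = edge_transition_matrix(edges, 0.7)
        assert (L.toarray() > 0).sum(axis=1).tolist() == [1] * 8

    def test_negative_h_rejected(self, toy):
        with pytest.raises(ValueError, match="nonnegative"):
            edge_transition_matrix(orient(toy), -0.1)


class TestSpectralRadius:
    def test_k4_nonbacktracking_growth_factor(self, k4):
        """A (d+1)-regular graph's non-backtracking matrix has growth
        factor d, cross-checked by brute-force path counting."""
        from volent import count_paths_series

        L = edge_transition_matrix(orient(k4), 0.0)
        assert spectral_radius(L) == pytest.approx(2.0, abs=1e-10)
        N = count_paths_series(k4, 0, 8)
        growth = [N[i + 1] / N[i] for i in range(4, 7)]
        assert np.allclose(growth, 2.0)

    def test_cycle_radius_is_edge_damping(self):
        net = cycle_graph(6, length=0.25)
        for h in (0.0, 1.0, 3.0):
            L = edge_transition_matrix(orient(net), h)
            assert spectral_radius(L) == pytest.approx(np.exp(-h * 0.25), rel=1e-12)

    def test_scalar_block(self):
        from scipy.sparse import csr_matrix

        assert spectral_radius(csr_matrix(np.array([[0.37]]))) == pytest.approx(0.37)

    def test_rejects_negative_matrix(self):
        with pytest.raises(ValueError, match="nonnegative"):
            spectral_radius(np.array([[0.0, -1.0], [1.0, 0.0]]))


class TestSolveVolumeEntropy:
    def test_cycle_entropy_zero_with_flag(self, c5):
        res = solve_volume_entropy(normalize_volume(c5))
        assert res.h_vol == 0.0
        assert res.non_expansive

    def test_k4_closed_form(self, k4_normalized):
        """(d+1)-regular equal-length graphs: h = ln(d) / l."""
        res = solve_volume_entropy(k4_normalized)
        assert res.h_vol == pytest.approx(6.0 * np.log(2.0), abs=1e-8)
        assert res.residual <= 1e-10

    def test_petersen_closed_form(self):
        net = normalize_volume(petersen_graph())
        l = net.lengths[0]
        res = solve_volume_entropy(net)
        assert res.h_vol == pytest.approx(np.log(2.0) / l, abs=1e-8)

    def test_toy_stationarity(self, toy):
        res = solve_volume_entropy(toy)
        assert res.residual <= 1e-10
        assert res.z.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(res.z > 0)
        # z is a fixed point of L(h_vol)
        L = edge_transition_matrix(res.edges, res.h_vol)
        np.testing.assert_allclose(L @ res.z, res.z, atol=1e-9)

    def test_stationarity_random_lengths(self, rng, toy):
        lengths = rng.uniform(0.3, 2.0, 12)
        from volent import toy_two_module_network

        net = toy_two_module_network(lengths=lengths)
        res = solve_volume_entropy(net)
        assert res.residual <= 1e-10
        assert res.z.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(res.z > 0)

    def test_scale_law(self, rng):
        """Multiplying all lengths by c divides the entropy by c."""
        from volent import toy_two_module_network

        lengths = rng.uniform(0.5, 1.5, 12)
        base = toy_two_module_network(lengths=lengths, normalized=False)
        c = 3.7
        scaled = WeightedNetwork(base.labels, base.edge_pairs, base.lengths * c)
        with pytest.warns(UserWarning, match="normalizing"):
            res1 = solve_volume_entropy(base, tol=1e-9)
            res2 = solve_volume_entropy(scaled, tol=1e-9)
        # both normalize to the same network
        assert res2.h_vol == pytest.approx(res1.h_vol, rel=1e-9)
        # and the unnormalized entropies obey the 1/c law
        assert res2.unnormalized_h_vol == pytest.approx(
            res1.unnormalized_h_vol / c, rel=1e-8
        )

    def test_relabeling_invariance(self, toy):
        mapping = {f"v{i}": f"w{(3 * i) % 7}" for i in range(1, 8)}
        relabeled = normalize_volume(toy.relabeled(mapping))
        r1 = solve_volume_entropy(toy)
        r2 = solve_volume_entropy(relabeled)
        assert r2.h_vol == pytest.approx(r1.h_vol, abs=1e-10)
        # edge capacities agree edge-by-edge under the relabeling
        Pi1 = edge_capacity_matrix(r1.z, r1.edges)
        Pi2 = edge_capacity_matrix(r2.z, r2.edges)
        for i, a in enumerate(toy.labels):
            for t, b in enumerate(toy.labels):
                i2 = relabeled.labels.index(mapping[a])
                t2 = relabeled.labels.index(mapping[b])
                assert Pi2[i2, t2] == pytest.approx(Pi1[i, t], abs=1e-10)

    def test_z_invariant_under_normalization(self, rng):
        """The stationary distribution does not depend on the volume
        normalization of the network."""
        net = toy_two_module_network_random(rng)
        raw = WeightedNetwork(net.labels, net.edge_pairs, net.lengths * 5.0)
        res_norm = solve_volume_entropy(net)
        with pytest.warns(UserWarning):
            res_raw = solve_volume_entropy(raw)
        np.testing.assert_allclose(res_raw.z, res_norm.z, atol=1e-9)

    def test_monotone_decreasing_spectral_radius(self, toy):
        edges = orient(toy)
        rhos = [
            spectral_radius(edge_transition_matrix(edges, h))
            for h in np.linspace(0.0, 20.0, 9)
        ]
        assert np.all(np.diff(rhos) < 0)


def toy_two_module_network_random(rng):
    from volent import toy_two_module_network

    return toy_two_module_network(lengths=rng.uniform(0.5, 1.5, 12))


class TestStationaryDistribution:
    def test_uniform_on_vertex_transitive_graphs(self):
        for net in (normalize_volume(complete_graph(4)), normalize_volume(petersen_graph())):
            res = solve_volume_entropy(net)
            np.testing.assert_allclose(res.z, 1.0 / res.q, atol=1e-12)

    def test_requires_unit_spectral_radius(self, toy):
        edges = orient(toy)
        with pytest.raises(ValueError, match="not 1"):
            stationary_distribution(edges, 0.0)

    def test_reducible_cycle_rejected(self):
        edges = orient(cycle_graph(5, length=0.2))
        with pytest.raises(RuntimeError, match="reducible"):
            stationary_distribution(edges, 0.0)

    def test_matches_power_iteration_oracle(self, toy):
        res = solve_volume_entropy(toy)
        L = edge_transition_matrix(res.edges, res.h_vol).toarray()
        v = np.ones(res.q) / res.q
        for _ in range(5000):
            v = L @ v
            v /= v.sum()
        np.testing.assert_allclose(res.z, v, atol=1e-9)


class TestCapacities:
    def test_k3_uniform_capacity(self):
        res = solve_volume_entropy(normalize_volume(complete_graph(3)))
        Pi = edge_capacity_matrix(res.z, res.edges)
        off = Pi[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / 6.0, atol=1e-12)

    def test_toy_capacity_matrix_shape(self, toy):
        res = solve_volume_entropy(toy)
        Pi = edge_capacity_matrix(res.z, res.edges)
        assert Pi.shape == (7, 7)
        np.testing.assert_allclose(np.diag(Pi), 0.0)
        assert (Pi > 0).sum() == 24
        assert Pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_toy_capacity_asymmetric(self, toy):
        res = solve_volume_entropy(toy)
        Pi = edge_capacity_matrix(res.z, res.edges)
        assert not np.allclose(Pi, Pi.T)

    def test_bridge_edges_flow_into_larger_module(self, toy):
        """More long paths exist inside the 4-clique than the 3-clique, so
        the stationary mass on each bridge edge oriented into the larger
        module exceeds its reverse."""
        res = solve_volume_entropy(toy)
        for u, v in TOY_BRIDGES:
            fwd = res.z[res.edges.index_of(u, v)]
            rev = res.z[res.edges.index_of(v, u)]
            assert fwd > rev

    def test_node_capacities_sum_to_zero(self, toy, rng):
        for _ in range(5):
            net = toy_two_module_network_random(rng)
            caps = capacity_tables(solve_volume_entropy(net))
            assert caps.node_capacity.sum() == pytest.approx(0.0, abs=1e-12)

    def test_node_capacities_vanish_on_vertex_transitive(self):
        res = solve_volume_entropy(normalize_volume(petersen_graph()))
        caps = node_capacities(edge_capacity_matrix(res.z, res.edges))
        np.testing.assert_allclose(caps, 0.0, atol=1e-12)

    def test_bridge_nodes_dominate_toy_capacities(self, toy):
        res = solve_volume_entropy(toy)
        caps = capacity_tables(res)
        by_label = dict(zip([str(l) for l in caps.labels], caps.node_capacity))
        # bridgeheads in the larger module absorb flow
        assert by_label["v4"] > 0 and by_label["v3"] > 0
        assert abs(by_label["v4"]) > abs(by_label["v1"])


class TestRescaling:
    def test_identity_at_volume_two(self):
        assert rescale_unnormalized_entropy(3.3, 2.0) == 3.3

    def test_direct_substitution(self):
        assert rescale_unnormalized_entropy(1.0, 4.0) == pytest.approx(0.5)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            rescale_unnormalized_entropy(1.0, 0.0)

    def test_matches_direct_unnormalized_solve(self, k4):
        """Solving with raw lengths (via the generalized root condition)
        agrees with rescaling the normalized solution."""
        from scipy.optimize import brentq

        res = solve_volume_entropy(normalize_volume(k4))
        rescaled = rescale_unnormalized_entropy(res.h_vol, k4.oriented_volume)
        edges = orient(k4)  # unit lengths, volume 12

        def g(h):
            return np.log(spectral_radius(edge_transition_matrix(edges, h)))

        direct = brentq(g, 1e-6, 10.0, xtol=1e-12)
        assert rescaled == pytest.approx(direct, abs=1e-8)

    @given(st.floats(0.2, 5.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rescaling_consistent_with_scale_law(self, c):
        # h(c * lengths) = h(lengths) / c, expressed through volumes
        h_norm = 2.0
        assert rescale_unnormalized_entropy(h_norm, 2.0 * c) == pytest.approx(
            rescale_unnormalized_entropy(h_norm, 2.0) / c
        )
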