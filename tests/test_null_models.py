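"""Randomized controls: conservation laws, determinism, sampling behavior."""
from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from richclubs import (
    RichnessSpec,
    WeightedNetwork,
    build_ensemble,
    degree_array,
    directed_weight_shuffle,
    er_weighted,
    mixed_control,
    strength_array,
    threshold_grid,
    topological_control,
    weighted_control,
)
from richclubs.null_models import child_seeds

from conftest import random_net

DEG = RichnessSpec("degree")


def edge_set(net: WeightedNetwork) -> set[tuple[int, int]]:
    return {tuple(e) for e in net.edges}


class TestTopologicalControl:
    @given(st.integers(0, 50))
    def test_degree_sequence_exactly_preserved(self, seed):
        net = random_net(seed)
        ctl = topological_control(net, seed=seed + 1)
        assert np.array_equal(degree_array(ctl), degree_array(net))
        assert np.all(ctl.weights == 1.0)

    def test_complete_graph_is_its_own_randomization(self):
        pairs = list(itertools.combinations("abcde", 2))
        net = WeightedNetwork.from_pairs(pairs)
        ctl = topological_control(net, seed=3)
        assert edge_set(ctl) == edge_set(net)

    def test_seed_determinism(self):
        net = random_net(7)
        a = topological_control(net, seed=11)
        b = topological_control(net, seed=11)
        assert np.array_equal(a.edges, b.edges)

    def test_requires_two_links(self):
        net = WeightedNetwork.from_edges([("a", "b", 1.0)])
        with pytest.raises(ValueError):
            topological_control(net, seed=0)

    def test_path_realizations_match_enumeration(self):
        """Swap-randomizing the path a-b-c-d samples the full set of simple
        graphs with the labeled degree sequence (1, 2, 2, 1)."""
        net = WeightedNetwork.from_pairs([("a", "b"), ("b", "c"), ("c", "d")])
        target = tuple(degree_array(net))
        labels = net.nodes
        all_pairs = list(itertools.combinations(range(4), 2))
        realizations = set()
        for k in range(len(all_pairs) + 1):
            for combo in itertools.combinations(all_pairs, k):
                deg = [0, 0, 0, 0]
                for u, v in combo:
                    deg[u] += 1
                    deg[v] += 1
                if tuple(deg) == target:
                    realizations.add(frozenset(combo))
        assert len(realizations) > 1  # the sequence is not uniquely realizable
        counts = {r: 0 for r in realizations}
        n_draws = 600
        for s in range(n_draws):
            ctl = topological_control(net, seed=s)
            counts[frozenset(edge_set(ctl))] += 1
        assert set(k for k, v in counts.items() if v > 0) == realizations
        # frequencies roughly balanced across realizations (loose check:
        # each within a factor ~2.5 of uniform)
        expect = n_draws / len(realizations)
        for r, c in counts.items():
            assert expect / 2.5 < c < expect * 2.5


class TestWeightedControl:
    @given(st.integers(0, 50))
    def test_topology_exactly_preserved(self, seed):
        net = random_net(seed)
        ctl = weighted_control(net, seed=seed + 1)
        assert np.array_equal(ctl.edges, net.edges)

    @given(st.integers(0, 50))
    def test_strengths_within_tolerance(self, seed):
        net = random_net(seed)
        tol = 1e-3
        ctl = weighted_control(net, seed=seed + 1, tol=tol)
        s0, s1 = strength_array(net), strength_array(ctl)
        ok = s0 > 0
        assert np.all(np.abs(s1[ok] - s0[ok]) / s0[ok] <= tol * 1.0001)
        assert ctl.total_weight == pytest.approx(net.total_weight, rel=2 * tol)

    def test_equal_weights_are_a_fixed_point(self):
        net = er_weighted(15, 0.5, seed=2).with_unit_weights()
        ctl = weighted_control(net, seed=9)
        assert np.allclose(ctl.weights, 1.0)

    def test_triangle_recovers_unique_solution(self):
        """On a triangle, strengths determine weights uniquely
        (w_ab = (s_a + s_b - s_c) / 2), so rescaling any permutation of
        {1, 2, 3} must return the original weights."""
        net = WeightedNetwork.from_edges(
            [("a", "b", 1.0), ("b", "c", 2.0), ("c", "a", 3.0)]
        )
        for seed in range(8):
            ctl = weighted_control(net, seed=seed, tol=1e-6)
            assert np.allclose(ctl.weights, net.weights, rtol=1e-4)

    def test_seed_determinism(self):
        net = random_net(3)
        a = weighted_control(net, seed=5)
        b = weighted_control(net, seed=5)
        assert np.array_equal(a.weights, b.weights)

    def test_weights_actually_decorrelated(self):
        """Permutation+rescaling should not reproduce the original
        weight-vs-degree-product correlation of a strongly correlated net."""
        net = er_weighted(40, 0.3, seed=4)
        deg = degree_array(net)
        kk = deg[net.edges[:, 0]] * deg[net.edges[:, 1]]
        # plant a strong weight-degree correlation
        w = 0.1 + kk / kk.max()
        net = net.with_weights(w)
        rho0 = np.corrcoef(net.weights, kk)[0, 1]
        rhos = [
            np.corrcoef(weighted_control(net, seed=s).weights, kk)[0, 1]
            for s in range(20)
        ]
        assert rho0 > 0.9
        assert np.mean(rhos) < rho0 - 0.2


class TestMixedControl:
    @given(st.integers(0, 30))
    def test_degree_sequence_preserved(self, seed):
        net = random_net(seed)
        ctl = mixed_control(net, seed=seed + 1)
        assert np.array_equal(degree_array(ctl), degree_array(net))

    def test_unit_weight_input_reduces_to_rewiring(self):
        net = er_weighted(15, 0.4, seed=6).with_unit_weights()
        ctl = mixed_control(net, seed=8)
        assert np.allclose(ctl.weights, 1.0, atol=1e-2)
        assert np.array_equal(degree_array(ctl), degree_array(net))

    @given(st.integers(0, 30))
    def test_strengths_within_tolerance(self, seed):
        net = random_net(seed)
        tol = 1e-3
        ctl = mixed_control(net, seed=seed + 1, tol=tol)
        s0, s1 = strength_array(net), strength_array(ctl)
        ok = s0 > 0
        assert np.all(np.abs(s1[ok] - s0[ok]) / s0[ok] <= tol * 1.0001)


class TestDirectedShuffle:
    @staticmethod
    def star(weights=(1.0, 2.0, 3.0)):
        net = WeightedNetwork.from_edges(
            [("hub", f"leaf{i}", w) for i, w in enumerate(weights)]
        )
        orientation = [("hub", f"leaf{i}") for i in range(len(weights))]
        return net, orientation

    def test_singleton_outgoing_weight_unchanged(self):
        net = WeightedNetwork.from_edges([("a", "b", 4.0), ("b", "c", 7.0)])
        ctl = directed_weight_shuffle(
            net, [("a", "b"), ("b", "c")], mode="outgoing", seed=1
        )
        # a and b each have exactly one outgoing link
        assert np.array_equal(ctl.weights, net.weights)

    @given(st.integers(0, 40))
    def test_out_strength_exactly_preserved(self, seed):
        net = random_net(seed)
        # orient every link from its lower-index endpoint
        orientation = [
            (net.nodes[u], net.nodes[v]) for u, v in net.edges
        ]
        ctl = directed_weight_shuffle(net, orientation, mode="outgoing", seed=seed)
        out0 = np.zeros(net.n_nodes)
        out1 = np.zeros(net.n_nodes)
        np.add.at(out0, net.edges[:, 0], net.weights)
        np.add.at(out1, ctl.edges[:, 0], ctl.weights)
        assert np.array_equal(np.sort(ctl.weights), np.sort(net.weights))
        assert np.allclose(out0, out1)

    def test_star_permutations_approximately_uniform(self):
        net, orientation = self.star()
        perms = {}
        n_draws = 1200
        for s in range(n_draws):
            ctl = directed_weight_shuffle(net, orientation, mode="outgoing", seed=s)
            perms[tuple(ctl.weights)] = perms.get(tuple(ctl.weights), 0) + 1
        assert len(perms) == 6  # all 3! assignments occur
        for count in perms.values():
            assert abs(count - n_draws / 6) < 4 * np.sqrt(n_draws * (1 / 6) * (5 / 6))

    def test_missing_orientation_is_an_error(self):
        net = WeightedNetwork.from_edges([("a", "b", 1.0), ("b", "c", 2.0)])
        with pytest.raises(ValueError, match="missing orientation"):
            directed_weight_shuffle(net, [("a", "b")], seed=0)


class TestBuildEnsemble:
    def test_same_seed_gives_bitwise_identical_ensembles(self):
        net = random_net(1, n=20, p=0.3)
        t = threshold_grid(net, DEG)
        for kind in ("topological", "weighted", "mixed"):
            a = build_ensemble(net, kind, t, DEG, n_rand=5, seed=99)
            b = build_ensemble(net, kind, t, DEG, n_rand=5, seed=99)
            assert np.array_equal(a.c_samples, b.c_samples)

    def test_thresholds_above_max_richness_give_zero_c(self):
        net = random_net(2, n=15, p=0.4)
        tmax = float(degree_array(net).max())
        ens = build_ensemble(net, "weighted", [tmax + 1], DEG, n_rand=3, seed=0)
        assert np.all(ens.c_samples == 0.0)

    def test_n_rand_validated(self):
        net = random_net(3)
        with pytest.raises(ValueError):
            build_ensemble(net, "weighted", [1.0], DEG, n_rand=0, seed=0)

    def test_child_seeds_are_distinct_and_bounded(self):
        s = child_seeds(123, 1000)
        assert len(set(s.tolist())) == 1000
        assert s.min() >= 0 and s.max() < 2**31

    def test_mean_c_rand_matches_independent_rewiring_loop(self):
        """Dual-route check: the ensemble's mean C_rand at a mid threshold
        agrees with an independently coded double-edge-swap loop."""
        rng = np.random.default_rng(12)
        net = er_weighted(25, 0.25, seed=12).with_unit_weights()
        t = float(np.median(degree_array(net)))
        n_rand = 300
        ens = build_ensemble(net, "topological", [t], DEG, n_rand=n_rand, seed=5)

        def swap_randomize(edges: set, n_swaps: int) -> set:
            edges = {tuple(e) for e in edges}
            for _ in range(n_swaps):
                (a, b), (c, d) = rng.choice(sorted(edges), 2, replace=False)
                if rng.random() < 0.5:
                    c, d = d, c
                new1 = tuple(sorted((a, c)))
                new2 = tuple(sorted((b, d)))
                if new1 == new2 or new1[0] == new1[1] or new2[0] == new2[1]:
                    continue
                if new1 in edges or new2 in edges:
                    continue
                edges -= {(min(a, b), max(a, b)), (min(c, d), max(c, d))}
                edges |= {new1, new2}
            return edges

        cs = []
        base = {tuple(e) for e in net.edges}
        for _ in range(n_rand):
            e2 = swap_randomize(base, 10 * len(base))
            deg = np.zeros(net.n_nodes)
            for u, v in e2:
                deg[u] += 1
                deg[v] += 1
            cs.append(sum(1 for u, v in e2 if deg[u] > t and deg[v] > t))
        mine, ref = ens.c_samples.mean(), np.mean(cs)
        se = np.sqrt(np.var(cs) / n_rand + ens.c_samples.var() / n_rand)
        assert abs(mine - ref) < 4 * se + 1e-9
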