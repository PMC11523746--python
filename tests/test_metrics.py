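"""Metric suite against hand values and independent oracles.

The implementations under test are first-principles; the oracles here are
either brute-force enumerations or networkx's library implementations,
neither of which shares code with the package.
"""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gridscan.generators import gen_complete, gen_small_world, gen_square_lattice
from gridscan.graph import make_graph
from gridscan.metrics import (
    avg_shortest_path_length,
    compute_metrics,
    random_reference,
    sigma,
    spectral_bipartivity,
    square_clustering,
    square_clustering_mean,
    transitivity,
    triangle_clustering_mean,
)

from conftest import random_test_graphs


def brute_transitivity(g):
    """Exhaustive triple enumeration (only viable for small graphs)."""
    nodes = list(g.nodes)
    triangles = sum(
        1 for a, b, c in combinations(nodes, 3)
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c)
    )
    triads = sum(d * (d - 1) // 2 for _, d in g.degree())
    return 0.0 if triads == 0 else 3 * triangles / triads


class TestTransitivity:
    def test_complete_graphs(self):
        for n in (9, 18, 27):
            assert transitivity(gen_complete(n)) == 1.0

    def test_square_lattices_are_triangle_free(self):
        for n in (3, 6, 9):
            assert transitivity(gen_square_lattice(n, n)) == 0.0

    def test_triangle_with_pendant(self, triangle_pendant):
        assert transitivity(triangle_pendant) == pytest.approx(0.6)

    def test_matches_enumeration_and_networkx(self):
        for g in random_test_graphs(30, 15, seed=21):
            t = transitivity(g)
            assert t == pytest.approx(brute_transitivity(g))
            assert t == pytest.approx(nx.transitivity(g))


class TestSquareClustering:
    def test_cycle_node_is_one(self, c4):
        assert square_clustering(c4, "a") == 1.0

    def test_star_hub_is_zero(self):
        star = make_graph(edges=[("h", "a"), ("h", "b"), ("h", "c")])
        assert square_clustering(star, "h") == 0.0

    def test_lattice_center(self):
        g = gen_square_lattice(3, 3)
        assert square_clustering(g, "(1, 1)") == pytest.approx(0.2)

    def test_mean_on_lattice_and_path(self, c4, path7):
        g = gen_square_lattice(3, 3)
        # per-node hand evaluation: 4 corners at 1/3, 4 edges at 1/4, center 0.2
        assert square_clustering_mean(g) == pytest.approx((4 / 3 + 1.0 + 0.2) / 9)
        assert square_clustering_mean(c4) == 1.0
        assert square_clustering_mean(path7) == 0.0  # square-free

    def test_matches_networkx_oracle(self):
        for g in random_test_graphs(30, 10, seed=33):
            if g.number_of_nodes() == 0:
                continue
            theirs = nx.square_clustering(g)
            for v in g.nodes:
                assert square_clustering(g, v) == pytest.approx(theirs[v])


class TestSpectralBipartivity:
    def test_square_lattices_exactly_one(self):
        for n in range(3, 10):
            assert spectral_bipartivity(gen_square_lattice(n, n)) == 1.0

    def test_triangle_value(self):
        # eigenvalues {2, -1, -1}: (cosh 2 + 2 cosh 1) / (e^2 + 2 e^-1)
        k3 = gen_complete(3)
        expected = (np.cosh(2) + 2 * np.cosh(1)) / (np.exp(2) + 2 * np.exp(-1))
        assert spectral_bipartivity(k3) == pytest.approx(expected)
        assert round(spectral_bipartivity(k3), 4) == 0.8429

    def test_complete_graph_near_half(self):
        assert round(spectral_bipartivity(gen_complete(9)), 2) == 0.50

    def test_one_iff_two_colorable(self):
        hits = 0
        for g in random_test_graphs(200, 12, seed=5):
            if g.number_of_edges() == 0:
                continue
            b = spectral_bipartivity(g)
            if nx.is_bipartite(g):  # BFS two-coloring oracle
                assert b == pytest.approx(1.0)
                hits += 1
            else:
                assert b < 1.0 - 1e-9
        assert hits > 5  # battery actually exercised both branches

    def test_matches_networkx_eigen_route(self):
        for g in random_test_graphs(20, 12, seed=55):
            if g.number_of_edges() == 0:
                continue
            assert spectral_bipartivity(g) == pytest.approx(
                nx.bipartite.spectral_bipartivity(g), abs=1e-8
            )

    def test_complete_graph_monotone_toward_half(self):
        values = [spectral_bipartivity(gen_complete(n)) for n in range(3, 31)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] > 0.5


class TestPathLength:
    def test_hand_values(self, path7):
        assert avg_shortest_path_length(make_graph(edges=[("a", "b")])) == 1.0
        abc = make_graph(edges=[("a", "b"), ("b", "c")])
        assert avg_shortest_path_length(abc) == pytest.approx(4 / 3)
        assert avg_shortest_path_length(gen_complete(11)) == 1.0

    def test_disconnected_instructs_caller(self):
        g = make_graph(edges=[("a", "b"), ("x", "y")])
        with pytest.raises(ValueError, match="component"):
            avg_shortest_path_length(g)

    def test_matches_networkx(self):
        for g in random_test_graphs(20, 12, seed=9, connected=True):
            assert avg_shortest_path_length(g) == pytest.approx(
                nx.average_shortest_path_length(g)
            )


class TestTriangleClustering:
    def test_hand_values(self, triangle_pendant):
        assert triangle_clustering_mean(gen_complete(9)) == 1.0
        assert triangle_clustering_mean(gen_square_lattice(4, 4)) == 0.0
        # per-node: two triangle corners at 1, the degree-3 corner at 1/3,
        # the pendant at 0 -> mean 7/12
        assert triangle_clustering_mean(triangle_pendant) == pytest.approx(7 / 12)

    def test_matches_networkx(self):
        for g in random_test_graphs(30, 12, seed=13):
            if g.number_of_nodes() == 0:
                continue
            assert triangle_clustering_mean(g) == pytest.approx(nx.average_clustering(g))


class TestRandomReference:
    def test_complete_graph_unchanged(self):
        k = gen_complete(9)
        ref = random_reference(k, seed=4)
        assert set(map(frozenset, ref.edges)) == set(map(frozenset, k.edges))

    def test_degree_sequence_preserved(self):
        for i, g in enumerate(random_test_graphs(15, 14, seed=17, connected=True)):
            if g.number_of_edges() < 2:
                continue
            ref = random_reference(g, seed=100 + i)
            assert dict(ref.degree()) == dict(g.degree())
            assert ref.number_of_edges() == g.number_of_edges()

    def test_seeded_determinism(self):
        g = gen_small_world(20, 4, 0.2, seed=1)
        a = random_reference(g, seed=7)
        b = random_reference(g, seed=7)
        assert set(a.edges) == set(b.edges)


class TestSigma:
    def test_square_lattice_zero_by_convention(self):
        for n in (3, 6, 9):
            assert sigma(gen_square_lattice(n, n), seed=1) == 0.0

    def test_complete_graph_exactly_one(self):
        # no legal swap exists, so references equal the input
        for n in (9, 27):
            assert sigma(gen_complete(n), seed=1) == 1.0

    def test_bit_reproducible(self):
        g = gen_small_world(20, 4, 0.1, seed=6)
        assert sigma(g, seed=12345) == sigma(g, seed=12345)

    def test_small_world_graphs_look_small_world(self):
        # matches the calibration table's sigma range for this model family
        wins = 0
        for s in range(20):
            g = gen_small_world(27, 6, 0.1, seed=s)
            if sigma(g, seed=s) > 1.0:
                wins += 1
        assert wins > 10

    def test_ring_lattice_beats_fully_rewired(self):
        wins = trials = 0
        for s in range(50):
            ring = gen_small_world(20, 4, 0.0, seed=s)
            rewired = gen_small_world(20, 4, 1.0, seed=s)
            if not nx.is_connected(rewired):
                continue
            trials += 1
            if sigma(ring, seed=s) > sigma(rewired, seed=s):
                wins += 1
        assert wins >= 0.8 * trials

    def test_rejects_disconnected_and_tiny(self):
        with pytest.raises(ValueError):
            sigma(make_graph(edges=[("a", "b"), ("x", "y")]), seed=0)
        with pytest.raises(ValueError):
            sigma(make_graph(edges=[("a", "b"), ("b", "c")]), seed=0)


class TestInvariances:
    def test_metrics_invariant_under_relabeling(self):
        rng = np.random.default_rng(99)
        for g in random_test_graphs(10, 10, seed=41, connected=True):
            perm = dict(zip(g.nodes, rng.permutation([f"r{i}" for i in range(len(g))])))
            h = nx.relabel_nodes(g, perm)
            assert transitivity(g) == pytest.approx(transitivity(h))
            assert square_clustering_mean(g) == pytest.approx(square_clustering_mean(h))
            assert spectral_bipartivity(g) == pytest.approx(spectral_bipartivity(h))
            assert avg_shortest_path_length(g) == pytest.approx(avg_shortest_path_length(h))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 7), st.integers(0, 7)).filter(lambda e: e[0] != e[1]),
            min_size=1,
            max_size=15,
        )
    )
    def test_fraction_metrics_stay_in_unit_interval(self, edges):
        g = make_graph(edges=[(str(a), str(b)) for a, b in edges])
        t = transitivity(g)
        c4 = square_clustering_mean(g)
        b = spectral_bipartivity(g)
        assert 0.0 <= t <= 1.0
        assert 0.0 <= c4 <= 1.0
        assert 0.5 <= b <= 1.0
        # transitivity vanishes exactly on triangle-free graphs
        assert (t == 0.0) == (brute_transitivity(g) == 0.0)


def test_compute_metrics_record_shape(c4):
    m = compute_metrics(c4, sigma_seed=1)
    assert (m.n_nodes, m.n_edges) == (4, 4)
    assert m.transitivity == 0.0
    assert m.bipartivity == 1.0
    assert m.sigma == 0.0
    assert m.avg_path_length == pytest.approx(4 / 3)
    tiny = compute_metrics(make_graph(edges=[("a", "b"), ("b", "c")]), sigma_seed=1)
    assert tiny.sigma is None
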