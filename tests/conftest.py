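import networkx as nx
import pytest

from gridscan.graph import make_graph


@pytest.fixture
def triangle_pendant():
    """A triangle with one pendant edge: 1 triangle, 5 triads, T = 0.6."""
    return make_graph(edges=[("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])


@pytest.fixture
def c4():
    """The minimal square grid: the 4-cycle."""
    return make_graph(edges=[("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


@pytest.fixture
def path7():
    """Path a-b-c-d-e-f-g."""
    labels = "abcdefg"
    return make_graph(edges=list(zip(labels, labels[1:])))


def random_test_graphs(n_graphs, max_nodes, seed, connected=False, min_nodes=2):
    """Deterministic battery of small random graphs for oracle comparisons."""
    import numpy as np

    rng = np.random.default_rng(seed)
    graphs = []
    while len(graphs) < n_graphs:
        n = int(rng.integers(min_nodes, max_nodes + 1))
        p = float(rng.uniform(0.1, 0.8))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {v: str(v) for v in g.nodes})
        if connected:
            if g.number_of_nodes() == 0 or not nx.is_connected(g):
                continue
        graphs.append(g)
    return graphs
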