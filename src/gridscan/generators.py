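"""Parameterized construction of the simulated network models.

Six model families calibrate the square-grid detector: complete graphs,
square lattices, triangular lattices, Erdős–Rényi random graphs,
Barabási–Albert preferential-attachment graphs and Watts–Strogatz
small-world graphs.  A seventh "hybrid" generator plants a square lattice
inside a background graph and is used to benchmark detector recovery.

Every generator is a pure function of its parameters (seed included): the
same call yields the identical graph, node labels and all.  Node labels are
strings, matching the connectome convention of the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import Graph

__all__ = [
    "GeneratorSpec",
    "gen_complete",
    "gen_square_lattice",
    "gen_triangular_lattice",
    "gen_random",
    "gen_preferential",
    "gen_small_world",
    "gen_hybrid",
    "build",
    "SQUARE_LATTICE_SIDES",
    "TRIANGULAR_LATTICE_DIMS",
]

#: Side lengths of the square-lattice calibration sweep (node counts 9..81).
SQUARE_LATTICE_SIDES: tuple[int, ...] = tuple(range(3, 10))

#: (rows, cols) of the triangular-lattice sweep.  Equal side lengths 3..9
#: step the node count from 10 to 55, inside the 9-81 calibration band.
TRIANGULAR_LATTICE_DIMS: tuple[tuple[int, int], ...] = tuple((m, m) for m in range(3, 10))


def _as_string_graph(g: nx.Graph) -> Graph:
    """Relabel arbitrary node objects to deterministic string IDs."""
    return nx.relabel_nodes(g, {v: str(v) for v in g.nodes}, copy=True)


def gen_complete(n: int) -> Graph:
    """Complete graph K_n: all node pairs connected; n(n-1)/2 edges."""
    if n < 2:
        raise ValueError(f"complete graph needs n >= 2, got {n}")
    return _as_string_graph(nx.complete_graph(n))


def gen_square_lattice(rows: int, cols: int) -> Graph:
    """Rectangular grid of rows x cols nodes; the idealized square-grid pattern.

    Edges join horizontally/vertically adjacent positions, giving
    ``rows*(cols-1) + cols*(rows-1)`` edges.  The graph is bipartite and
    triangle-free for every size; (2, 2) is the minimal square grid, the
    4-cycle C4.
    """
    if rows < 2 or cols < 2:
        raise ValueError(f"lattice dimensions must be >= 2, got ({rows}, {cols})")
    return _as_string_graph(nx.grid_2d_graph(rows, cols))


def gen_triangular_lattice(rows: int, cols: int) -> Graph:
    """Planar triangular lattice; the triangle-rich counterpart to the square grid."""
    if rows < 2 or cols < 2:
        raise ValueError(f"triangular lattice dimensions must be >= 2, got ({rows}, {cols})")
    g = nx.triangular_lattice_graph(rows, cols)
    # drop positional metadata; topology is all that matters downstream
    for _, data in g.nodes(data=True):
        data.clear()
    return _as_string_graph(g)


def gen_random(n: int, p: float, seed: int) -> Graph:
    """Erdős–Rényi G(n, p).  Low p may yield a disconnected graph; callers
    analyzing path-based metrics take the largest component."""
    if n < 2:
        raise ValueError(f"random graph needs n >= 2, got {n}")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"edge probability must be in (0, 1], got {p}")
    return _as_string_graph(nx.gnp_random_graph(n, p, seed=seed))


def gen_preferential(n: int, m_attach: int, seed: int) -> Graph:
    """Barabási–Albert growth: each new node attaches ``m_attach`` edges to
    existing nodes with probability proportional to degree.

    Edge count is exactly ``(n - m_attach) * m_attach``.
    """
    if not 1 <= m_attach < n:
        raise ValueError(f"need 1 <= m_attach < n, got m_attach={m_attach}, n={n}")
    return _as_string_graph(nx.barabasi_albert_graph(n, m_attach, seed=seed))


def gen_small_world(n: int, k: int, p: float, seed: int) -> Graph:
    """Watts–Strogatz ring of ``n`` nodes, each joined to its ``k`` nearest
    neighbors, then every edge rewired with probability ``p``.

    ``k`` must be even (the ring construction joins k/2 neighbors on each
    side); odd values are rejected rather than silently rounded.
    """
    if k % 2 != 0:
        raise ValueError(f"ring-neighbor count k must be even, got {k}")
    if k >= n:
        raise ValueError(f"need k < n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"rewiring probability must be in [0, 1], got {p}")
    return _as_string_graph(nx.watts_strogatz_graph(n, k, p, seed=seed))


def gen_hybrid(
    lattice_rows: int,
    lattice_cols: int,
    background: "GeneratorSpec",
    n_bridges: int,
    seed: int,
) -> tuple[Graph, set[str]]:
    """Plant a square lattice inside a background graph.

    The lattice and the background are disjoint; ``n_bridges`` randomly
    chosen lattice-to-background edges join them.  Returns the combined
    graph and the planted lattice node set, for recovery benchmarks.
    Lattice nodes are prefixed ``L:`` and background nodes ``B:`` so the
    two parts can never collide.
    """
    if n_bridges < 1:
        raise ValueError(f"need n_bridges >= 1, got {n_bridges}")
    lattice = gen_square_lattice(lattice_rows, lattice_cols)
    bg = build(background)
    g = nx.Graph()
    planted = {f"L:{v}" for v in lattice.nodes}
    g.add_nodes_from(planted)
    g.add_edges_from((f"L:{u}", f"L:{v}") for u, v in lattice.edges)
    g.add_nodes_from(f"B:{v}" for v in bg.nodes)
    g.add_edges_from((f"B:{u}", f"B:{v}") for u, v in bg.edges)
    rng = np.random.default_rng(seed)
    lat_nodes = sorted(planted)
    bg_nodes = sorted(f"B:{v}" for v in bg.nodes)
    for _ in range(n_bridges):
        u = lat_nodes[rng.integers(len(lat_nodes))]
        v = bg_nodes[rng.integers(len(bg_nodes))]
        g.add_edge(u, v)
    return g, planted


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one simulated network.

    ``model`` selects the family; only the parameters that family uses are
    read.  Lattice models take (rows, cols); stochastic models take a seed.
    """

    model: str  # complete | square_grid | triangular_grid | random | preferential | small_world
    n: int = 0
    rows: int = 0
    cols: int = 0
    p: float = 0.0
    m_attach: int = 1
    k: int = 4
    seed: int = 0
    label: str = field(default="", compare=False)

    def describe(self) -> str:
        return self.label or f"{self.model}(n={self.n or self.rows * self.cols})"


def build(spec: GeneratorSpec) -> Graph:
    """Materialize a :class:`GeneratorSpec` into a graph."""
    m = spec.model
    if m == "complete":
        return gen_complete(spec.n)
    if m == "square_grid":
        return gen_square_lattice(spec.rows, spec.cols)
    if m == "triangular_grid":
        return gen_triangular_lattice(spec.rows, spec.cols)
    if m == "random":
        return gen_random(spec.n, spec.p, spec.seed)
    if m == "preferential":
        return gen_preferential(spec.n, spec.m_attach, spec.seed)
    if m == "small_world":
        return gen_small_world(spec.n, spec.k, spec.p, spec.seed)
    raise ValueError(f"unknown generator model {m!r}")
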