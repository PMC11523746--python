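"""Core undirected simple-graph model.

Neuronal networks are represented as :class:`networkx.Graph` instances over
opaque string node identifiers (neuron body IDs can exceed 32-bit integer
range, so IDs are never treated as numbers).  Edges are synaptic connections
collapsed to simple undirected links: no self-loops, no parallel edges, no
direction, no weights.

All other modules consume graphs through the small operation set defined
here; anything window-related builds on :func:`ego_window`.
"""

from __future__ import annotations

from collections import deque
from collections.abc import Iterable, Set

import networkx as nx

__all__ = [
    "Graph",
    "make_graph",
    "degree",
    "connected_components",
    "induced_subgraph",
    "ego_window",
]

#: The graph container used throughout the package.
Graph = nx.Graph


class UnknownNodeError(KeyError):
    """Raised when an operation references a node absent from the graph."""

    def __init__(self, node: str) -> None:
        super().__init__(node)
        self.node = node

    def __str__(self) -> str:  # KeyError repr-quotes its arg; we want a message
        return f"node {self.node!r} is not in the graph"


def make_graph(nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()) -> Graph:
    """Build a simple undirected graph, coercing node IDs to ``str``.

    Self-loops in ``edges`` are rejected; duplicate pairs collapse under set
    semantics (that is ``networkx.Graph`` behaviour).
    """
    g = nx.Graph()
    g.add_nodes_from(str(v) for v in nodes)
    for u, v in edges:
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"self-loop on node {u!r} not allowed")
        g.add_edge(u, v)
    return g


def degree(g: Graph, v: str) -> int:
    """Number of distinct neighbors of ``v``."""
    if v not in g:
        raise UnknownNodeError(v)
    return g.degree(v)


def connected_components(g: Graph) -> list[set[str]]:
    """Connected components, largest first.

    Ties in size are broken by the lexicographically smallest member ID so
    the ordering is deterministic regardless of node insertion order.
    """
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def induced_subgraph(g: Graph, s: Set[str] | Iterable[str]) -> Graph:
    """Subgraph induced on node set ``s`` (a detached copy, not a view)."""
    s = set(s)
    missing = s - set(g.nodes)
    if missing:
        raise UnknownNodeError(sorted(missing)[0])
    return nx.Graph(g.subgraph(s))


def ego_window(g: Graph, v: str, radius: int = 2) -> set[str]:
    """Closed ``radius``-hop neighborhood of ``v``.

    The detection window of the sliding-window scan: the node of interest,
    its adjacent neighbors, and (at the default radius 2) all adjacent
    neighbors of those neighbors.  The induced subgraph on the result is
    always connected because every member lies on a path from ``v``.
    """
    if v not in g:
        raise UnknownNodeError(v)
    if radius < 1:
        raise ValueError("radius must be a positive integer")
    seen = {v}
    frontier = deque([(v, 0)])
    while frontier:
        node, d = frontier.popleft()
        if d == radius:
            continue
        for w in g.neighbors(node):
            if w not in seen:
                seen.add(w)
                frontier.append((w, d + 1))
    return seen
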