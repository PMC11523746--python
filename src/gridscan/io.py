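"""Connectome edge-list input, scan reports, and graph export.

Connectome data arrives as delimited text where each record is a connected
pair of neurons (the fruit-fly hemibrain per-region files are the
motivating dialect).  Records are collapsed to an undirected simple graph:
direction, synapse weights, duplicate pairs and self-loops do not enter the
topological analysis, but dropped-record counts are logged so provenance is
not silently lost.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd

from .graph import Graph
from .scan import (
    ComponentRejection,
    Criteria,
    component_filter,
    gridness_percent,
    gridness_score,
    overlap_clusters,
    scan,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeListDialect",
    "DEFAULT_DIALECT",
    "HEMIBRAIN_DIALECT",
    "DIALECTS",
    "read_edge_list",
    "ScanReport",
    "run_scan",
    "write_report",
    "read_report",
    "export_graphml",
]


@dataclass(frozen=True)
class EdgeListDialect:
    """How to interpret one edge-list file.

    Columns are addressed by name when ``header`` is true, otherwise by
    zero-based index (pass the index as a string, e.g. ``"0"``).
    """

    delimiter: str = ","
    source: str = "source"
    target: str = "target"
    roi: str | None = None
    weight: str | None = None
    header: bool = True

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("source and target columns must differ")


DEFAULT_DIALECT = EdgeListDialect()
#: The hemibrain v1.1 per-ROI export layout.
HEMIBRAIN_DIALECT = EdgeListDialect(
    source="bodyId_pre", target="bodyId_post", roi="roi", weight="weight"
)
DIALECTS = {"default": DEFAULT_DIALECT, "hemibrain": HEMIBRAIN_DIALECT}


def read_edge_list(path: str | Path, dialect: EdgeListDialect = DEFAULT_DIALECT) -> Graph:
    """Parse a delimited neuron-pair file into an undirected simple graph.

    Neuron IDs are kept as strings end to end.  Self-loops and duplicate
    pairs (in either orientation) are dropped with logged counts; a weight
    column, if present, is ignored for topology.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        header=0 if dialect.header else None,
        dtype=str,
        skipinitialspace=True,
    )
    if df.empty and df.columns.size == 0:
        logger.warning("edge list %s is empty; returning the empty graph", path)
        return nx.Graph()
    if dialect.header:
        for col in (dialect.source, dialect.target):
            if col not in df.columns:
                raise ValueError(
                    f"{path}: column {col!r} not found (columns: {list(df.columns)})"
                )
        src, tgt = df[dialect.source], df[dialect.target]
    else:
        si, ti = int(dialect.source), int(dialect.target)
        if max(si, ti) >= df.shape[1]:
            raise ValueError(f"{path}: fewer than {max(si, ti) + 1} columns")
        src, tgt = df.iloc[:, si], df.iloc[:, ti]
    g = nx.Graph()
    n_self = n_dup = 0
    header_offset = 2 if dialect.header else 1
    for i, (u, v) in enumerate(zip(src, tgt)):
        if pd.isna(u) or pd.isna(v) or str(u).strip() == "" or str(v).strip() == "":
            raise ValueError(f"{path}, line {i + header_offset}: malformed record ({u!r}, {v!r})")
        u, v = str(u).strip(), str(v).strip()
        if u == v:
            n_self += 1
            continue
        if g.has_edge(u, v):
            n_dup += 1
            continue
        g.add_edge(u, v)
    if n_self or n_dup:
        logger.info(
            "%s: dropped %d self-loop and %d duplicate records (%d edges kept)",
            path, n_self, n_dup, g.number_of_edges(),
        )
    return g


@dataclass
class ScanReport:
    """Full result of one component scan, serializable to TSV/JSON."""

    input_id: str
    component_sizes: list[int]
    accepted_size: int  # 0 when every component was rejected
    n_windows: int
    n_flagged: int
    n_clusters: int
    n_singletons: int
    gridness_fraction: float
    gridness_pct: int
    grid_nodes: list[str] = field(default_factory=list)  # union over cluster node sets
    windows: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def run_scan(
    g: Graph,
    criteria: Criteria = Criteria(),
    seed: int = 0,
    input_id: str = "network",
) -> ScanReport:
    """Full pipeline: component filter -> window scan -> overlap clusters -> score."""
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    comp = component_filter(g, criteria)
    if isinstance(comp, ComponentRejection):
        return ScanReport(
            input_id=input_id,
            component_sizes=sizes,
            accepted_size=0,
            n_windows=0,
            n_flagged=0,
            n_clusters=0,
            n_singletons=0,
            gridness_fraction=0.0,
            gridness_pct=0,
        )
    windows = scan(comp, criteria, sigma_seed=seed)
    clusters, singletons = overlap_clusters(windows)
    frac = gridness_score(comp, clusters)
    grid_nodes: set[str] = set()
    cluster_of: dict[str, int] = {}
    for ci, c in enumerate(clusters):
        grid_nodes |= c.node_union
        for w in c.windows:
            cluster_of[w.center] = ci
    rows = []
    for w in windows:
        m = w.metrics
        rows.append(
            {
                "center": w.center,
                "n_nodes": m.n_nodes,
                "n_edges": m.n_edges,
                "transitivity": m.transitivity,
                "square_clustering_mean": m.square_clustering_mean,
                "bipartivity": m.bipartivity,
                "sigma": m.sigma,
                "flagged": w.flagged,
                "cluster_id": cluster_of.get(w.center, -1),
            }
        )
    return ScanReport(
        input_id=input_id,
        component_sizes=sizes,
        accepted_size=comp.number_of_nodes(),
        n_windows=len(windows),
        n_flagged=sum(1 for w in windows if w.flagged),
        n_clusters=len(clusters),
        n_singletons=len(singletons),
        gridness_fraction=frac,
        gridness_pct=gridness_percent(frac),
        grid_nodes=sorted(grid_nodes),
        windows=rows,
    )


_SUMMARY_FIELDS = [
    "input_id", "component_sizes", "accepted_size", "n_windows", "n_flagged",
    "n_clusters", "n_singletons", "gridness_fraction", "gridness_pct",
]


def write_report(report: ScanReport, path: str | Path, fmt: str = "json") -> None:
    """Write a scan report as JSON (lossless, round-trips) or TSV.

    The TSV form has one row per window followed by a ``__summary__`` row;
    field ordering is deterministic in both formats.
    """
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=False) + "\n")
    elif fmt == "tsv":
        df = pd.DataFrame(
            report.windows,
            columns=[
                "center", "n_nodes", "n_edges", "transitivity",
                "square_clustering_mean", "bipartivity", "sigma",
                "flagged", "cluster_id",
            ],
        )
        summary = {k: "" for k in df.columns}
        summary["center"] = "__summary__"
        summary["cluster_id"] = json.dumps(
            {k: getattr(report, k) for k in _SUMMARY_FIELDS}
        )
        df = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r} (use 'json' or 'tsv')")


def read_report(path: str | Path) -> ScanReport:
    """Read back a JSON scan report."""
    data = json.loads(Path(path).read_text())
    return ScanReport(**data)


def export_graphml(g: Graph, flagged_nodes: set[str], path: str | Path) -> None:
    """Write GraphML with a boolean ``grid_member`` node attribute.

    Replaces by-eye window inspection: any GraphML viewer can color the
    nodes that participate in a detected square-grid arrangement.
    """
    unknown = set(flagged_nodes) - set(g.nodes)
    if unknown:
        raise ValueError(f"flagged nodes not in graph: {sorted(unknown)[:5]}")
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    out.add_edges_from(g.edges)
    for v in out.nodes:
        out.nodes[v]["grid_member"] = v in flagged_nodes
    nx.write_graphml(out, str(path))
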