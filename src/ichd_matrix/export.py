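"""Graph exports for external visualization (Cytoscape-compatible).

Emits SIF (whitespace-delimited ``source interaction target``), GraphML
(typed attributes, re-readable) and a node-attribute CSV.  A phenotype
and a characteristic with identical text can never collide: node ids
carry the axis prefixes used throughout the package (``p:`` / ``c:``).
Ordering is deterministic (sorted labels).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .matrix import BiadjacencyMatrix
from .mcl import CHARACTERISTIC_PREFIX, PHENOTYPE_PREFIX, Clustering
from .projection import ProjectionGraph

__all__ = [
    "bipartite_edges",
    "projection_edges",
    "node_table",
    "export_sif",
    "export_graphml",
    "export_node_csv",
]


def bipartite_edges(m: BiadjacencyMatrix) -> list[tuple[str, str, int, str]]:
    """(source, target, weight=1, type='bipartite') for every 1 cell."""
    edges = []
    for i, rlabel in enumerate(m.row_labels):
        for j, clabel in enumerate(m.col_labels):
            if m.values[i, j]:
                edges.append(
                    (PHENOTYPE_PREFIX + rlabel, CHARACTERISTIC_PREFIX + clabel, 1,
                     "bipartite")
                )
    return sorted(edges)


def projection_edges(g: ProjectionGraph) -> list[tuple[str, str, int, str]]:
    prefix = PHENOTYPE_PREFIX if g.axis == "phenotypes" else CHARACTERISTIC_PREFIX
    return sorted(
        (prefix + u, prefix + v, w, "projection") for (u, v), w in g.edges.items()
    )


def node_table(
    m: BiadjacencyMatrix | None = None,
    projection: ProjectionGraph | None = None,
    clustering: Clustering | None = None,
) -> pd.DataFrame:
    """Node attribute table: id, label, axis, and optional cluster id."""
    records: dict[str, dict] = {}
    if m is not None:
        for l in m.row_labels:
            records[PHENOTYPE_PREFIX + l] = {"label": l, "axis": "phenotype"}
        for l in m.col_labels:
            records[CHARACTERISTIC_PREFIX + l] = {"label": l, "axis": "characteristic"}
    if projection is not None:
        prefix, axis = (
            (PHENOTYPE_PREFIX, "phenotype")
            if projection.axis == "phenotypes"
            else (CHARACTERISTIC_PREFIX, "characteristic")
        )
        for l in projection.nodes:
            records.setdefault(prefix + l, {"label": l, "axis": axis})
    if clustering is not None:
        membership = clustering.membership()
        for node_id, rec in records.items():
            if node_id in membership:
                rec["cluster"] = membership[node_id]
    rows = [
        {"id": node_id, **rec} for node_id, rec in sorted(records.items())
    ]
    return pd.DataFrame(rows, columns=["id", "label", "axis", "cluster"]
                        if clustering is not None else ["id", "label", "axis"])


def export_sif(
    edges: list[tuple[str, str, int, str]], path: str | Path
) -> None:
    """SIF: one ``source interaction target`` line per edge (tab-delimited;
    the interaction slot carries the edge type)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for source, target, _w, etype in edges:
            fh.write(f"{source}\t{etype}\t{target}\n")


def _graph_from_edges(
    edges: list[tuple[str, str, int, str]], nodes: pd.DataFrame | None
) -> nx.Graph:
    g = nx.Graph()
    if nodes is not None:
        for rec in nodes.to_dict("records"):
            attrs = {k: v for k, v in rec.items() if k != "id" and pd.notna(v)}
            g.add_node(rec["id"], **attrs)
    for source, target, weight, etype in edges:
        g.add_edge(source, target, weight=int(weight), type=etype)
    return g


def export_graphml(
    edges: list[tuple[str, str, int, str]],
    path: str | Path,
    nodes: pd.DataFrame | None = None,
) -> None:
    nx.write_graphml(_graph_from_edges(edges, nodes), str(path))


def export_node_csv(nodes: pd.DataFrame, path: str | Path) -> None:
    nodes.to_csv(path, index=False)
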