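"""Weighted one-mode projections of the bipartite criteria graph.

Projecting onto phenotypes links two matrix rows with weight equal to the
number of characteristics they share ((M M^T) off-diagonal); projecting
onto characteristics links two columns by the number of phenotypes in
which they co-occur (M^T M).  Zero-weight pairs are absent edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .matrix import BiadjacencyMatrix

__all__ = ["ProjectionGraph", "project", "top_weight_pairs"]


@dataclass(frozen=True)
class ProjectionGraph:
    axis: str  # "phenotypes" | "characteristics"
    nodes: tuple[str, ...]
    # unordered pairs keyed as (u, v) with u < v lexicographically
    edges: dict[tuple[str, str], int]

    def weight(self, u: str, v: str) -> int:
        key = (u, v) if u < v else (v, u)
        return self.edges.get(key, 0)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((u, v, w) for (u, v), w in self.edges.items())
        return g


def project(m: BiadjacencyMatrix, axis: str) -> ProjectionGraph:
    """One-mode projection of the biadjacency matrix.

    ``axis='phenotypes'`` uses M·Mᵀ, ``axis='characteristics'`` uses Mᵀ·M;
    the diagonal is discarded and zero entries are absent edges.  Weights
    are exact integers.
    """
    if axis == "phenotypes":
        labels = m.row_labels
        b = sp.csr_matrix(m.values.astype(np.int64))
    elif axis == "characteristics":
        labels = m.col_labels
        b = sp.csr_matrix(m.values.astype(np.int64).T)
    else:
        raise ValueError(f"axis must be 'phenotypes' or 'characteristics', got {axis!r}")
    w = (b @ b.T).tocoo()
    edges: dict[tuple[str, str], int] = {}
    for i, j, val in zip(w.row, w.col, w.data):
        if i < j and val > 0:
            u, v = labels[i], labels[j]
            key = (u, v) if u < v else (v, u)
            edges[key] = int(val)
    return ProjectionGraph(axis=axis, nodes=tuple(labels), edges=edges)


def top_weight_pairs(
    g: ProjectionGraph, rank: int
) -> tuple[int, list[tuple[str, str]]]:
    """The ``rank``-th largest *distinct* weight and all pairs attaining it.

    "Second highest weight" means the second largest distinct value (one
    value may be attained by many pairs), not the weight of the
    second-ranked edge.  Pairs are returned sorted lexicographically.
    """
    if rank < 1:
        raise ValueError(f"rank must be a positive integer, got {rank}")
    distinct = sorted(set(g.edges.values()), reverse=True)
    if rank > len(distinct):
        raise ValueError(
            f"rank {rank} exceeds the number of distinct weights ({len(distinct)})"
        )
    w = distinct[rank - 1]
    pairs = sorted(pair for pair, weight in g.edges.items() if weight == w)
    return w, pairs
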