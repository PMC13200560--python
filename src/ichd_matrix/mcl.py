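"""Markov clustering of the criteria graph with modularity-guided
parameter selection.

The bipartite phenotype–characteristic graph is clustered with the
standard MCL loop (van Dongen): add self-loops, column-normalize to a
stochastic matrix, then alternate *expansion* (matrix power ``e``,
simulating flow along random walks) and *inflation* (elementwise power
``r`` followed by column renormalization, sharpening the flow) with
pruning of near-zero entries, until the iterate stops changing.
Clusters are read off the attractor rows.  Expansion and inflation are
chosen by sweeping a grid and scoring each clustering with Newman–Girvan
modularity on the (unipartite view of the) graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .matrix import BiadjacencyMatrix

__all__ = [
    "MCLParams",
    "Clustering",
    "SweepResult",
    "bipartite_to_adjacency",
    "mcl",
    "modularity",
    "sweep",
    "select_parameters",
    "PHENOTYPE_PREFIX",
    "CHARACTERISTIC_PREFIX",
]

# axis disambiguation for node labels in the unipartite view
PHENOTYPE_PREFIX = "p:"
CHARACTERISTIC_PREFIX = "c:"


@dataclass(frozen=True)
class MCLParams:
    """Tunable MCL parameters.

    Defaults follow common reference-library practice: self-loop weight 1
    added before normalization (required for convergence), pruning at
    1e-5, convergence tolerance 1e-8, at most 100 iterations.
    """

    expansion: int = 2
    inflation: float = 2.0
    self_loop_weight: float = 1.0
    prune_threshold: float = 1e-5
    convergence_tol: float = 1e-8
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if not (isinstance(self.expansion, (int, np.integer)) and self.expansion >= 2):
            raise ValueError(f"expansion must be an integer >= 2, got {self.expansion!r}")
        if not self.inflation > 1:
            raise ValueError(f"inflation must be > 1, got {self.inflation!r}")
        if self.self_loop_weight < 0:
            raise ValueError("self_loop_weight must be >= 0")


@dataclass(frozen=True)
class Clustering:
    clusters: tuple[frozenset[str], ...]
    params: MCLParams
    converged: bool
    iterations: int

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, int]:
        """Node -> index of its first-listed cluster (overlaps resolved
        deterministically in favour of the earlier cluster)."""
        out: dict[str, int] = {}
        for idx, cluster in enumerate(self.clusters):
            for node in cluster:
                out.setdefault(node, idx)
        return out


def bipartite_to_adjacency(
    m: BiadjacencyMatrix,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Symmetric 0/1 adjacency over phenotype and characteristic nodes.

    Block structure [[0, M], [Mᵀ, 0]]; phenotype labels are prefixed with
    ``p:`` and characteristic labels with ``c:`` so the two axes can never
    collide.  Phenotype–phenotype and characteristic–characteristic
    blocks are all-zero by construction (the graph is bipartite).
    """
    n_r, n_c = m.shape
    labels = tuple(PHENOTYPE_PREFIX + l for l in m.row_labels) + tuple(
        CHARACTERISTIC_PREFIX + l for l in m.col_labels
    )
    adj = np.zeros((n_r + n_c, n_r + n_c), dtype=np.float64)
    adj[:n_r, n_r:] = m.values
    adj[n_r:, :n_r] = m.values.T
    return labels, adj


def _column_normalize(mat: np.ndarray) -> np.ndarray:
    sums = mat.sum(axis=0)
    sums[sums == 0] = 1.0
    return mat / sums


def mcl(
    adjacency: np.ndarray,
    labels: tuple[str, ...] | list[str],
    params: MCLParams | None = None,
    iteration_callback=None,
) -> Clustering:
    """Run Markov clustering on a symmetric non-negative adjacency matrix.

    Clusters are the nonzero supports of attractor rows (rows with a
    nonzero diagonal entry in the converged iterate); identical clusters
    are merged and any node left uncovered (a rare MCL artifact) becomes
    its own singleton so that every node appears in at least one cluster.
    Non-convergence within ``max_iterations`` yields a best-effort
    clustering flagged ``converged=False``.
    """
    params = params or MCLParams()
    adjacency = np.asarray(adjacency, dtype=np.float64)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    if adjacency.shape[0] != len(labels):
        raise ValueError("labels length must match adjacency dimension")
    if (adjacency < 0).any():
        raise ValueError("adjacency must be non-negative")
    if not np.allclose(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    n = adjacency.shape[0]
    if n == 0:
        return Clustering((), params, True, 0)

    mat = adjacency + params.self_loop_weight * np.eye(n)
    mat = _column_normalize(mat)
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        prev = mat
        mat = np.linalg.matrix_power(mat, params.expansion)  # expand
        np.power(mat, params.inflation, out=mat)  # inflate
        mat = _column_normalize(mat)
        mat[mat < params.prune_threshold] = 0.0  # prune
        mat = _column_normalize(mat)
        if iteration_callback is not None:
            iteration_callback(iterations, mat)
        if prev.shape == mat.shape and np.abs(mat - prev).max() < params.convergence_tol:
            converged = True
            break

    clusters: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for i in np.flatnonzero(np.diagonal(mat) > 0):
        cluster = frozenset(labels[j] for j in np.flatnonzero(mat[i] > 0))
        if cluster and cluster not in seen:
            seen.add(cluster)
            clusters.append(cluster)
    covered = set().union(*clusters) if clusters else set()
    for label in labels:
        if label not in covered:
            singleton = frozenset({label})
            if singleton not in seen:
                seen.add(singleton)
                clusters.append(singleton)
    return Clustering(tuple(clusters), params, converged, iterations)


def modularity(
    adjacency: np.ndarray, clustering: Clustering | dict[str, int], labels=None
) -> float:
    """Newman–Girvan modularity of a clustering on the unipartite graph.

    Q = Σ_c [L_c/m − (d_c/(2m))²] with L_c the intra-cluster edge weight,
    d_c the summed degree of the cluster and m the total edge weight.
    Overlapping nodes count toward their first-listed cluster only.
    Raises on an edgeless graph (Q undefined).
    """
    adjacency = np.asarray(adjacency, dtype=np.float64)
    if isinstance(clustering, Clustering):
        if labels is None:
            raise ValueError("labels are required when passing a Clustering")
        member_by_label = clustering.membership()
        missing = [l for l in labels if l not in member_by_label]
        if missing:
            raise ValueError(f"clustering does not cover node(s) {missing[:3]}")
        member = np.array([member_by_label[l] for l in labels])
    else:
        if labels is None:
            raise ValueError("labels are required")
        member = np.array([clustering[l] for l in labels])
    two_m = adjacency.sum()
    if two_m == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    degrees = adjacency.sum(axis=1)
    q = 0.0
    for c in np.unique(member):
        idx = member == c
        l_c = adjacency[np.ix_(idx, idx)].sum() / 2.0
        d_c = degrees[idx].sum()
        q += l_c / (two_m / 2.0) - (d_c / two_m) ** 2
    return float(q)


@dataclass(frozen=True)
class SweepResult:
    vary: str  # "inflation" | "expansion"
    grid: tuple[float, ...]
    q_values: tuple[float, ...]
    n_clusters: tuple[int, ...]
    best: float  # argmax grid value (ties -> smallest)

    def as_rows(self) -> list[tuple[float, float, int]]:
        return list(zip(self.grid, self.q_values, self.n_clusters))


def sweep(
    adjacency: np.ndarray,
    labels,
    vary: str,
    grid,
    fixed: MCLParams | None = None,
) -> SweepResult:
    """Run MCL at each grid value of one parameter and score modularity.

    Returns the full Q-curve together with the argmax grid value (ties
    broken toward the smallest parameter value).
    """
    if vary not in {"inflation", "expansion"}:
        raise ValueError(f"vary must be 'inflation' or 'expansion', got {vary!r}")
    grid = tuple(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    fixed = fixed or MCLParams()
    qs: list[float] = []
    counts: list[int] = []
    for value in grid:
        params = replace(
            fixed,
            **{vary: int(value) if vary == "expansion" else float(value)},
        )
        clustering = mcl(adjacency, labels, params)
        qs.append(modularity(adjacency, clustering, labels))
        counts.append(clustering.n_clusters)
    best_idx = min(range(len(grid)), key=lambda i: (-qs[i], grid[i]))
    return SweepResult(
        vary=vary,
        grid=tuple(float(v) for v in grid),
        q_values=tuple(qs),
        n_clusters=tuple(counts),
        best=float(grid[best_idx]),
    )


DEFAULT_INFLATION_GRID = tuple(round(1.5 + 0.1 * i, 1) for i in range(36))  # 1.5..5.0
DEFAULT_EXPANSION_GRID = tuple(range(2, 10))  # 2..9


def select_parameters(
    adjacency: np.ndarray,
    labels,
    inflation_grid=DEFAULT_INFLATION_GRID,
    expansion_grid=DEFAULT_EXPANSION_GRID,
    base: MCLParams | None = None,
) -> tuple[MCLParams, SweepResult, SweepResult]:
    """Two-stage protocol: sweep inflation at expansion 2, then sweep
    expansion at the chosen inflation.  Returns the selected parameters
    and both Q-curves."""
    base = base or MCLParams()
    infl = sweep(adjacency, labels, "inflation", inflation_grid,
                 replace(base, expansion=2))
    exp = sweep(adjacency, labels, "expansion", expansion_grid,
                replace(base, inflation=infl.best))
    chosen = replace(base, inflation=infl.best, expansion=int(exp.best))
    return chosen, infl, exp
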