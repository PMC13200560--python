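"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (exhaustive enumeration, pure
Python loops, no shared code with the package's computational paths) so
that agreement is meaningful.
"""

from __future__ import annotations

import itertools
from math import isclose

from ichd_matrix.criteria import BoolExpr, evaluate, expr_variables


# ------------------------------------------------------------------ DNF

def truth_table_equivalent(expr: BoolExpr, clauses: list[frozenset[str]]) -> bool:
    """Exhaustively check: expr is true iff some clause is fully true,
    over all 2^n assignments of the expression's variables."""
    variables = expr_variables(expr)
    extra = set().union(*clauses) - set(variables) if clauses else set()
    assert not extra, f"DNF mentions variables absent from the expression: {extra}"
    for bits in itertools.product([False, True], repeat=len(variables)):
        present = {v for v, b in zip(variables, bits) if b}
        direct = evaluate(expr, present)
        via_dnf = any(clause <= present for clause in clauses)
        if direct != via_dnf:
            return False
    return True


def is_subsumption_free(clauses: list[frozenset[str]]) -> bool:
    return not any(
        a < b for a in clauses for b in clauses
    ) and len(set(clauses)) == len(clauses)


# ----------------------------------------------------------- projection

def brute_force_projection(row_labels, col_labels, values, axis):
    """Shared-neighbor counting with explicit set intersections."""
    if axis == "phenotypes":
        labels = list(row_labels)
        neighborhoods = [
            {col_labels[j] for j in range(len(col_labels)) if values[i][j]}
            for i in range(len(row_labels))
        ]
    else:
        labels = list(col_labels)
        neighborhoods = [
            {row_labels[i] for i in range(len(row_labels)) if values[i][j]}
            for j in range(len(col_labels))
        ]
    edges = {}
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            w = len(neighborhoods[a] & neighborhoods[b])
            if w:
                u, v = sorted((labels[a], labels[b]))
                edges[(u, v)] = w
    return edges


# ----------------------------------------------------------- modularity

def modularity_by_edge_counting(edges, membership):
    """Q from explicit edge enumeration: Q = sum_c [L_c/m - (d_c/2m)^2].

    ``edges`` is an iterable of (u, v) pairs (no self-loops), and
    ``membership`` maps node -> cluster id.
    """
    edges = list(edges)
    m = len(edges)
    if m == 0:
        raise ValueError("edgeless graph")
    clusters = set(membership.values())
    q = 0.0
    for c in clusters:
        l_c = sum(1 for u, v in edges if membership[u] == c and membership[v] == c)
        d_c = sum((membership[u] == c) + (membership[v] == c) for u, v in edges)
        q += l_c / m - (d_c / (2 * m)) ** 2
    return q


# ------------------------------------------------------------------ MCL

def naive_mcl(adjacency, expansion=2, inflation=2.0, self_loop=1.0,
              prune=1e-5, tol=1e-8, max_iter=100):
    """Pure-Python Markov clustering: column-stochastic flow matrix,
    alternate expansion (matrix power) and inflation (elementwise power +
    renormalization) with pruning, read clusters from attractor rows.

    Returns a set of frozensets of node indices.
    """
    n = len(adjacency)
    mat = [[float(adjacency[i][j]) + (self_loop if i == j else 0.0)
            for j in range(n)] for i in range(n)]

    def normalize(m_):
        for j in range(n):
            s = sum(m_[i][j] for i in range(n))
            if s:
                for i in range(n):
                    m_[i][j] /= s
        return m_

    def matmul(a, b):
        bt = list(zip(*b))
        return [[sum(x * y for x, y in zip(row, col)) for col in bt] for row in a]

    mat = normalize(mat)
    for _ in range(max_iter):
        prev = [row[:] for row in mat]
        power = mat
        for _ in range(expansion - 1):
            power = matmul(power, mat)
        mat = [[x ** inflation for x in row] for row in power]
        mat = normalize(mat)
        mat = [[x if x >= prune else 0.0 for x in row] for row in mat]
        mat = normalize(mat)
        delta = max(
            abs(mat[i][j] - prev[i][j]) for i in range(n) for j in range(n)
        )
        if delta < tol:
            break
    clusters = set()
    for i in range(n):
        if mat[i][i] > 0:
            clusters.add(frozenset(j for j in range(n) if mat[i][j] > 0))
    covered = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in covered:
            clusters.add(frozenset({i}))
    return clusters


# ----------------------------------------------------------------- rank

def numerical_rank(values, tol=1e-9):
    import numpy as np

    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return 0
    singular = np.linalg.svd(arr, compute_uv=False)
    return int((singular > tol).sum())
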