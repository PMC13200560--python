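"""Exact row reduction: the vector space spanned by headache phenotypes.

Every phenotype row is a 0/1 vector over characteristics; reduced row
echelon form (RREF) identifies the pivot columns — the minimal set of
*basis characteristics* whose linear combinations span every phenotype.
Elimination is carried out in exact rational arithmetic: 0/1 matrices
produce fractions mid-elimination and floating-point error could flip
the rank, so no floats appear anywhere in the computation.  Internally a
fraction-free integer scheme (cross-multiplication with per-row gcd
reduction) is used and rows are normalized to leading ones only at the
end.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd

import numpy as np

from .matrix import BiadjacencyMatrix, submatrix_excluding

__all__ = ["RrefResult", "rref", "rref_array", "basis_characteristics"]


@dataclass(frozen=True)
class RrefResult:
    pivot_columns: tuple[str, ...]  # labels, in original column order
    rank: int
    reduced: tuple[tuple[Fraction, ...], ...]  # full RREF, exact rationals

    def __post_init__(self) -> None:
        assert self.rank == len(self.pivot_columns)


def _row_reduce_exact(
    rows: list[list[int]], n_cols: int
) -> tuple[list[int], list[list[Fraction]]]:
    """Return (pivot column indices, RREF rows as Fractions).

    Pivot policy: first nonzero column left-to-right, first available row
    top-to-bottom — no magnitude heuristics, so the pivot column set is
    deterministic for a given column order.
    """
    work = [list(map(int, r)) for r in rows]
    n_rows = len(work)
    pivots: list[int] = []
    r = 0
    for col in range(n_cols):
        pivot_row = next((i for i in range(r, n_rows) if work[i][col] != 0), None)
        if pivot_row is None:
            continue
        work[r], work[pivot_row] = work[pivot_row], work[r]
        p = work[r][col]
        prow = work[r]
        for i in range(n_rows):
            if i == r:
                continue
            q = work[i][col]
            if q == 0:
                continue
            row = work[i]
            for j in range(col, n_cols):
                row[j] = row[j] * p - prow[j] * q
            g = 0
            for x in row:
                g = gcd(g, x)
            if g > 1:
                for j in range(n_cols):
                    row[j] //= g
        pivots.append(col)
        r += 1
        if r == n_rows:
            break
    reduced: list[list[Fraction]] = []
    for i, row in enumerate(work):
        lead = next((x for x in row if x != 0), None)
        if lead is None:
            reduced.append([Fraction(0)] * n_cols)
        else:
            reduced.append([Fraction(x, lead) for x in row])
    return pivots, reduced


def rref_array(values: np.ndarray) -> tuple[list[int], list[list[Fraction]]]:
    """Exact RREF of an integer array; returns pivot indices and rows."""
    arr = np.asarray(values)
    rows = [[int(x) for x in row] for row in arr]
    n_cols = arr.shape[1] if arr.ndim == 2 else 0
    return _row_reduce_exact(rows, n_cols)


def rref(m: BiadjacencyMatrix) -> RrefResult:
    """Exact reduced row echelon form of the biadjacency matrix.

    Pivot columns are reported by characteristic label in the matrix's
    declared column order.  Note that while the rank is invariant under
    any row/column permutation, pivot-column *identity* depends on column
    order; the declared order is therefore part of the result's contract.
    """
    pivots, reduced = rref_array(m.values)
    return RrefResult(
        pivot_columns=tuple(m.col_labels[j] for j in pivots),
        rank=len(pivots),
        reduced=tuple(tuple(row) for row in reduced),
    )


def basis_characteristics(
    m: BiadjacencyMatrix,
    include_probable: bool = False,
    probable_prefix: str = "probable",
) -> tuple[str, ...]:
    """Pivot (basis) characteristics of the phenotype space.

    With ``include_probable=False``, rows whose label begins with
    ``probable_prefix`` (the row-naming convention for ICHD-3 "probable"
    diagnoses) are dropped before reduction, giving the basis for
    definitive diagnoses only.
    """
    if not include_probable:
        m = submatrix_excluding(m, lambda label: label.startswith(probable_prefix))
    return rref(m).pivot_columns
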