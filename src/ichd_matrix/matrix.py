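"""The phenotype × characteristic biadjacency matrix and its CSV codec.

Rows are phenotypes (conjunctive clauses of disorder criteria), columns
are characteristics; cell (X, Y) is 1 iff phenotype X contains
characteristic Y.  The matrix is the biadjacency matrix of the bipartite
phenotype–characteristic graph and is small enough (hundreds by
hundreds) that a dense uint8 array is the canonical representation.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .criteria import CriteriaSet, canonical_label
from .dnf import enumerate_phenotypes

__all__ = [
    "BiadjacencyMatrix",
    "MatrixFormatError",
    "build_matrix",
    "read_matrix_csv",
    "write_matrix_csv",
    "row_sums",
    "submatrix_excluding",
    "ReconcileReport",
    "reconcile",
]


class MatrixFormatError(ValueError):
    """Raised for malformed matrix CSV content."""


@dataclass(frozen=True)
class BiadjacencyMatrix:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray  # uint8, shape (len(row_labels), len(col_labels))

    def __post_init__(self) -> None:
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        vals = np.asarray(self.values)
        if vals.shape != (len(self.row_labels), len(self.col_labels)):
            raise MatrixFormatError(
                f"value shape {vals.shape} does not match labels "
                f"({len(self.row_labels)} x {len(self.col_labels)})"
            )
        if vals.size and not np.isin(vals, (0, 1)).all():
            bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
            raise MatrixFormatError(
                f"non-binary entry at row {self.row_labels[bad[0]]!r}, "
                f"column {self.col_labels[bad[1]]!r}"
            )
        object.__setattr__(self, "values", vals.astype(np.uint8))
        for axis_name, labels in (("row", self.row_labels), ("column", self.col_labels)):
            if len(set(labels)) != len(labels):
                seen: set[str] = set()
                dup = next(l for l in labels if l in seen or seen.add(l))  # type: ignore[func-returns-value]
                raise MatrixFormatError(f"duplicate {axis_name} label {dup!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.row_labels), columns=list(self.col_labels)
        )

    def row(self, label: str) -> np.ndarray:
        return self.values[self.row_labels.index(label)]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.col_labels.index(label)]


def build_matrix(cs: CriteriaSet) -> BiadjacencyMatrix:
    """Expand every disorder and assemble the 0/1 matrix.

    Rows are the concatenation of each disorder's phenotypes in
    declaration order; columns follow the universe order of ``cs``.
    """
    phenotypes = [p for d in cs.disorders for p in enumerate_phenotypes(d)]
    col_index = {c: j for j, c in enumerate(cs.universe)}
    values = np.zeros((len(phenotypes), len(cs.universe)), dtype=np.uint8)
    for i, p in enumerate(phenotypes):
        for label in p.characteristics:
            values[i, col_index[label]] = 1
    m = BiadjacencyMatrix(
        row_labels=tuple(p.name for p in phenotypes),
        col_labels=tuple(cs.universe),
        values=values,
    )
    if m.shape[0] and (m.values.sum(axis=1) == 0).any():
        raise MatrixFormatError("built matrix contains an all-zero row")
    return m


# --------------------------------------------------------------------------
# CSV codec
# --------------------------------------------------------------------------

def write_matrix_csv(m: BiadjacencyMatrix, path: str | Path) -> None:
    """Comma-delimited, header row of characteristic labels, leading
    phenotype-label column, 0/1 integer cells."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["", *m.col_labels])
        for label, row in zip(m.row_labels, m.values):
            writer.writerow([label, *(int(x) for x in row)])


def read_matrix_csv(path: str | Path) -> BiadjacencyMatrix:
    """Read a labelled 0/1 matrix CSV.

    Tolerates quoted labels, a UTF-8 BOM, and either comma or semicolon
    delimiters (sniffed from the header line).  Raises
    :class:`MatrixFormatError` with cell coordinates for non-binary
    entries and for duplicate labels.
    """
    text = Path(path).read_text(encoding="utf-8-sig")
    if not text.strip():
        return BiadjacencyMatrix((), (), np.zeros((0, 0), dtype=np.uint8))
    header_line = text.splitlines()[0]
    try:
        dialect = csv.Sniffer().sniff(header_line, delimiters=",;")
        delimiter = dialect.delimiter
    except csv.Error:
        delimiter = ","
    rows = list(csv.reader(io.StringIO(text), delimiter=delimiter))
    rows = [r for r in rows if r and any(cell.strip() for cell in r)]
    header = rows[0]
    col_labels = [canonical_label(c) for c in header[1:]]
    row_labels: list[str] = []
    data: list[list[int]] = []
    for r in rows[1:]:
        label = canonical_label(r[0])
        if len(r) - 1 != len(col_labels):
            raise MatrixFormatError(
                f"row {label!r} has {len(r) - 1} cells, expected {len(col_labels)}"
            )
        parsed: list[int] = []
        for j, cell in enumerate(r[1:]):
            cell = cell.strip()
            if cell not in {"0", "1"}:
                raise MatrixFormatError(
                    f"non-binary cell {cell!r} at row {label!r}, "
                    f"column {col_labels[j]!r}"
                )
            parsed.append(int(cell))
        row_labels.append(label)
        data.append(parsed)
    values = (
        np.array(data, dtype=np.uint8)
        if data
        else np.zeros((0, len(col_labels)), dtype=np.uint8)
    )
    return BiadjacencyMatrix(tuple(row_labels), tuple(col_labels), values)


# --------------------------------------------------------------------------
# Row utilities
# --------------------------------------------------------------------------

def row_sums(m: BiadjacencyMatrix) -> np.ndarray:
    """Number of ones per row (the phenotype's characteristic count)."""
    return m.values.sum(axis=1).astype(np.int64)


def submatrix_excluding(
    m: BiadjacencyMatrix, predicate: Callable[[str], bool]
) -> BiadjacencyMatrix:
    """Drop rows whose label matches ``predicate``; columns are preserved
    in full and in order."""
    keep = [i for i, label in enumerate(m.row_labels) if not predicate(label)]
    return BiadjacencyMatrix(
        row_labels=tuple(m.row_labels[i] for i in keep),
        col_labels=m.col_labels,
        values=m.values[keep] if keep else np.zeros((0, m.shape[1]), dtype=np.uint8),
    )


# --------------------------------------------------------------------------
# Reconciliation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReconcileReport:
    """Difference report between two matrices, insensitive to row/column
    permutation (labels are matched after canonicalization)."""

    rows_only_in_built: tuple[str, ...]
    rows_only_in_reference: tuple[str, ...]
    cols_only_in_built: tuple[str, ...]
    cols_only_in_reference: tuple[str, ...]
    cell_mismatches: tuple[tuple[str, str], ...]  # (row, col) on the common grid

    @property
    def ok(self) -> bool:
        return not (
            self.rows_only_in_built
            or self.rows_only_in_reference
            or self.cols_only_in_built
            or self.cols_only_in_reference
            or self.cell_mismatches
        )

    def summary(self) -> str:
        if self.ok:
            return "matrices agree (up to row/column permutation)"
        parts = []
        for name, items in [
            ("rows only in built", self.rows_only_in_built),
            ("rows only in reference", self.rows_only_in_reference),
            ("columns only in built", self.cols_only_in_built),
            ("columns only in reference", self.cols_only_in_reference),
            ("cell mismatches", self.cell_mismatches),
        ]:
            if items:
                parts.append(f"{name}: {len(items)}")
        return "; ".join(parts)


def reconcile(built: BiadjacencyMatrix, reference: BiadjacencyMatrix) -> ReconcileReport:
    """Compare a built matrix against a reference instance.

    Labels present on only one side are listed; cells are compared on the
    common label sub-grid.  Equality up to row/column permutation is the
    pass condition (``report.ok``).
    """
    brows, rrows = set(built.row_labels), set(reference.row_labels)
    bcols, rcols = set(built.col_labels), set(reference.col_labels)
    common_rows = sorted(brows & rrows)
    common_cols = sorted(bcols & rcols)
    bi = {l: i for i, l in enumerate(built.row_labels)}
    ri = {l: i for i, l in enumerate(reference.row_labels)}
    bj = {l: j for j, l in enumerate(built.col_labels)}
    rj = {l: j for j, l in enumerate(reference.col_labels)}
    mismatches = [
        (r, c)
        for r in common_rows
        for c in common_cols
        if built.values[bi[r], bj[c]] != reference.values[ri[r], rj[c]]
    ]
    return ReconcileReport(
        rows_only_in_built=tuple(sorted(brows - rrows)),
        rows_only_in_reference=tuple(sorted(rrows - brows)),
        cols_only_in_built=tuple(sorted(bcols - rcols)),
        cols_only_in_reference=tuple(sorted(rcols - bcols)),
        cell_mismatches=tuple(mismatches),
    )
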