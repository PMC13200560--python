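"""Automated diagnosis by the row-sum theorem.

A patient's answers form a 0/1 vector v over the characteristic columns
(unanswered characteristics count as 0; there is no three-valued logic).
A phenotype row is satisfied exactly when (M·v) for that row equals the
row's sum — i.e. every characteristic the phenotype requires is present
— which is equivalent to direct Boolean evaluation of the disorder's
criteria formula.  All satisfied phenotypes are reported: the engine
applies no exclusivity rule, since the "not better accounted for"
criterion is deliberately outside the matrix, so concurrent diagnoses
are legitimate output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .criteria import canonical_label
from .matrix import BiadjacencyMatrix, row_sums

__all__ = [
    "ResponseVector",
    "DiagnosisResult",
    "UnknownCharacteristicError",
    "diagnose",
    "contradiction_check",
    "disorder_of_row",
]

_TRAILING_INDEX_RE = re.compile(r"^(.*?)(\d+)$")


class UnknownCharacteristicError(ValueError):
    """A response references characteristics outside the matrix universe."""

    def __init__(self, offenders: list[str]):
        self.offenders = offenders
        super().__init__(
            "response contains characteristic(s) not in the matrix: "
            + ", ".join(repr(o) for o in offenders)
        )


@dataclass(frozen=True)
class ResponseVector:
    """Patient responses: characteristic label -> 0/1; unlisted labels are 0."""

    answers: Mapping[str, int]

    def __post_init__(self) -> None:
        canon: dict[str, int] = {}
        for label, value in self.answers.items():
            if value not in (0, 1, True, False):
                raise ValueError(
                    f"response for {label!r} must be 0 or 1, got {value!r}"
                )
            canon[canonical_label(label)] = int(value)
        object.__setattr__(self, "answers", canon)

    @property
    def present(self) -> frozenset[str]:
        return frozenset(l for l, v in self.answers.items() if v == 1)

    def as_array(self, col_labels: tuple[str, ...]) -> np.ndarray:
        index = {c: j for j, c in enumerate(col_labels)}
        offenders = sorted(l for l in self.answers if l not in index)
        if offenders:
            raise UnknownCharacteristicError(offenders)
        v = np.zeros(len(col_labels), dtype=np.int64)
        for label, value in self.answers.items():
            v[index[label]] = value
        return v


def disorder_of_row(row_label: str) -> str:
    """Strip the 1-based phenotype index from a row label: ``ndph1`` -> ``ndph``."""
    match = _TRAILING_INDEX_RE.match(row_label)
    return match.group(1) if match else row_label


@dataclass(frozen=True)
class DiagnosisResult:
    satisfied_phenotypes: tuple[str, ...]  # row labels, matrix order
    diagnosed_disorders: tuple[str, ...]  # slug order of first satisfied row
    scores: dict[str, float]  # row label -> (M v)_i / rowsum_i, partial-match triage


def diagnose(m: BiadjacencyMatrix, v: ResponseVector) -> DiagnosisResult:
    """Match a response vector against every phenotype row.

    Row i is satisfied iff (M·v)_i equals the i-th row sum of M.  The
    per-row match score (M·v)_i / rowsum_i is exposed for triage of near
    misses but plays no part in the diagnosis decision.
    """
    vec = v.as_array(m.col_labels)
    products = m.values.astype(np.int64) @ vec
    sums = row_sums(m)
    satisfied = [
        label
        for label, p, s in zip(m.row_labels, products, sums)
        if s > 0 and p == s
    ]
    disorders: dict[str, None] = {}
    for label in satisfied:
        disorders.setdefault(disorder_of_row(label))
    scores = {
        label: (float(p) / float(s) if s else 0.0)
        for label, p, s in zip(m.row_labels, products, sums)
    }
    return DiagnosisResult(
        satisfied_phenotypes=tuple(satisfied),
        diagnosed_disorders=tuple(disorders),
        scores=scores,
    )


def contradiction_check(m: BiadjacencyMatrix | None, v: ResponseVector) -> list[str]:
    """Warn when both a characteristic and its "no "-prefixed counterpart
    are answered 1 (e.g. "photophobia" and "no photophobia").

    Purely advisory; never blocks diagnosis.  When a matrix is given the
    check is restricted to its column universe.
    """
    present = set(v.present)
    if m is not None:
        present &= set(m.col_labels)
    warnings = []
    for label in sorted(present):
        negated = f"no {label}"
        if negated in present:
            warnings.append(
                f"both {label!r} and {negated!r} are marked present"
            )
    return warnings
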