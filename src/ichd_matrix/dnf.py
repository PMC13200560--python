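"""Disjunctive-normal-form expansion of disorder criteria.

Each conjunctive clause of a disorder's DNF is one *phenotype*: a single
way a patient can satisfy the criteria, and one row of the biadjacency
matrix.  Because the formula fragment is negation-free, the subsumption-
free expansion (no clause a superset of another) is exactly the set of
prime implicants — "at least two of four" contributes the six pairs, not
all supersets — and general Boolean minimization is unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass

from .criteria import And, AtLeast, BoolExpr, Disorder, Or, Var
from itertools import combinations

__all__ = ["Phenotype", "to_dnf", "enumerate_phenotypes"]


def _minimize(clauses: list[frozenset[str]]) -> list[frozenset[str]]:
    """Remove duplicate clauses and clauses subsumed by a subset clause."""
    kept: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for clause in sorted(set(clauses), key=len):
        if any(k <= clause for k in kept):
            continue
        if clause not in seen:
            kept.append(clause)
            seen.add(clause)
    return kept


def _canonical_order(clauses: list[frozenset[str]]) -> list[frozenset[str]]:
    # lexicographic over the sorted label tuple: deterministic and
    # insensitive to the order OR children were declared in
    return sorted(clauses, key=lambda c: tuple(sorted(c)))


def _dnf(expr: BoolExpr) -> list[frozenset[str]]:
    if isinstance(expr, Var):
        return [frozenset({expr.label})]
    if isinstance(expr, Or):
        out: list[frozenset[str]] = []
        for child in expr.children:
            out.extend(_dnf(child))
        return _minimize(out)
    if isinstance(expr, AtLeast):
        labels = sorted({c.label for c in expr.children})
        k = min(expr.k, len(labels))  # duplicate children collapse
        return [frozenset(sub) for sub in combinations(labels, k)]
    if isinstance(expr, And):
        acc: list[frozenset[str]] = [frozenset()]
        for child in expr.children:
            child_clauses = _dnf(child)
            acc = _minimize([a | c for a in acc for c in child_clauses])
        return acc
    raise TypeError(f"not a BoolExpr node: {expr!r}")


def to_dnf(expr: BoolExpr) -> list[frozenset[str]]:
    """Expand ``expr`` into its subsumption-free DNF.

    Returns characteristic-label sets, one per conjunctive clause, in a
    deterministic canonical order (lexicographic over sorted label
    tuples).  For every truth assignment the formula is true iff some
    returned set is entirely true, and no returned set is a superset of
    another.
    """
    return _canonical_order(_dnf(expr))


@dataclass(frozen=True)
class Phenotype:
    """One conjunctive clause of a disorder: a matrix row.

    ``name`` is the disorder slug followed by a 1-based index in canonical
    clause order (``ndph1``, ``migrainewoaura3``, ...).
    """

    name: str
    disorder_id: str
    characteristics: frozenset[str]


def enumerate_phenotypes(d: Disorder) -> list[Phenotype]:
    """All phenotypes of a disorder, named ``<id><index>`` in DNF order."""
    clauses = to_dnf(d.expr)
    if not clauses:  # unreachable for a valid negation-free expr
        raise RuntimeError(f"disorder {d.id!r} expanded to an empty DNF")
    return [
        Phenotype(name=f"{d.id}{i}", disorder_id=d.id, characteristics=clause)
        for i, clause in enumerate(clauses, start=1)
    ]
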