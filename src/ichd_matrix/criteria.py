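"""Boolean criteria model for headache disorders.

The ICHD-3 defines each primary headache disorder by a list of lettered
criteria over clinical *characteristics* — Boolean variables such as
"photophobia" or "4 to 72 h".  A disorder is a negation-free Boolean
formula over these variables built from AND, OR and "at least k of n"
connectives (negative clinical statements such as "no photophobia" are
modelled as separate positive variables, never with a NOT operator).

This module provides the formula AST, label canonicalization, a YAML
codec for criteria files and structural validation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

import yaml

__all__ = [
    "canonical_label",
    "Var",
    "And",
    "Or",
    "AtLeast",
    "BoolExpr",
    "Disorder",
    "CriteriaSet",
    "Issue",
    "CriteriaError",
    "expr_from_obj",
    "expr_to_obj",
    "expr_variables",
    "evaluate",
    "load_criteria",
    "save_criteria",
    "validate",
]


class CriteriaError(ValueError):
    """Raised for malformed criteria files or invalid formula structure."""


def canonical_label(label: str) -> str:
    """Canonical form of a characteristic label.

    Lower-cases, trims, and collapses internal whitespace.  No stemming or
    synonym folding is performed: ICHD-3 synonym pairs ("continuous" /
    "constant") are resolved at encoding time, not here.  Idempotent.
    """
    if not isinstance(label, str):
        raise CriteriaError(f"characteristic label must be a string, got {label!r}")
    out = " ".join(label.split()).lower()
    if not out:
        raise CriteriaError("characteristic label must be non-empty")
    return out


# --------------------------------------------------------------------------
# Formula AST
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Var:
    """A single characteristic reference (leaf)."""

    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", canonical_label(self.label))


@dataclass(frozen=True)
class And:
    children: tuple["BoolExpr", ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(self.children))
        if len(self.children) < 1:
            raise CriteriaError("AND requires at least one child")


@dataclass(frozen=True)
class Or:
    children: tuple["BoolExpr", ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(self.children))
        if len(self.children) < 1:
            raise CriteriaError("OR requires at least one child")


@dataclass(frozen=True)
class AtLeast:
    """At least ``k`` of the listed characteristics are present.

    Children are restricted to plain variables, matching the way ICHD-3
    phrases these criteria ("at least two of the following four
    characteristics").
    """

    k: int
    children: tuple[Var, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(self.children))
        if any(not isinstance(c, Var) for c in self.children):
            raise CriteriaError("ATLEAST children must be plain characteristics")
        if not isinstance(self.k, int) or not 1 <= self.k <= len(self.children):
            raise CriteriaError(
                f"ATLEAST k={self.k!r} out of range 1..{len(self.children)}"
            )


BoolExpr = Union[Var, And, Or, AtLeast]


def _walk(expr: BoolExpr) -> Iterator[BoolExpr]:
    yield expr
    if isinstance(expr, (And, Or, AtLeast)):
        for child in expr.children:
            yield from _walk(child)


def expr_variables(expr: BoolExpr) -> list[str]:
    """Distinct characteristic labels in first-appearance order."""
    seen: dict[str, None] = {}
    for node in _walk(expr):
        if isinstance(node, Var):
            seen.setdefault(node.label)
    return list(seen)


def evaluate(expr: BoolExpr, present: Iterable[str]) -> bool:
    """Evaluate ``expr`` under the truth assignment where exactly the
    characteristics in ``present`` are true."""
    truth = {canonical_label(p) for p in present}

    def ev(node: BoolExpr) -> bool:
        if isinstance(node, Var):
            return node.label in truth
        if isinstance(node, And):
            return all(ev(c) for c in node.children)
        if isinstance(node, Or):
            return any(ev(c) for c in node.children)
        if isinstance(node, AtLeast):
            return sum(c.label in truth for c in node.children) >= node.k
        raise TypeError(f"not a BoolExpr node: {node!r}")

    return ev(expr)


# --------------------------------------------------------------------------
# Disorders and criteria sets
# --------------------------------------------------------------------------

_SLUG_RE = re.compile(r"^[a-z][a-z0-9]*$")


@dataclass(frozen=True)
class Disorder:
    """One ICHD-3 diagnosis: a named, negation-free Boolean formula.

    ``id`` is the short slug used as the row-name prefix in the matrix
    (e.g. ``ndph`` -> rows ``ndph1``, ``ndph2``, ...).  ``probable`` flags
    ICHD-3 "probable" categories (presentations missing one criterion),
    which the basis computation can exclude.
    """

    id: str
    name: str
    expr: BoolExpr
    probable: bool = False

    def __post_init__(self) -> None:
        if not _SLUG_RE.match(self.id):
            raise CriteriaError(
                f"disorder id {self.id!r} must be a lowercase alphanumeric slug"
            )


@dataclass(frozen=True)
class CriteriaSet:
    """An ordered collection of disorders over a shared characteristic universe."""

    disorders: tuple[Disorder, ...]
    universe: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "disorders", tuple(self.disorders))
        object.__setattr__(
            self, "universe", tuple(canonical_label(u) for u in self.universe)
        )
        ids = [d.id for d in self.disorders]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise CriteriaError(f"duplicate disorder id(s): {sorted(dup)}")
        if len(set(self.universe)) != len(self.universe):
            seen: set[str] = set()
            dups = [u for u in self.universe if u in seen or seen.add(u)]  # type: ignore[func-returns-value]
            raise CriteriaError(f"duplicate characteristic(s) in universe: {dups}")
        known = set(self.universe)
        for d in self.disorders:
            missing = [v for v in expr_variables(d.expr) if v not in known]
            if missing:
                raise CriteriaError(
                    f"disorder {d.id!r} references characteristic(s) outside the "
                    f"universe: {missing}"
                )

    @classmethod
    def from_disorders(
        cls, disorders: Iterable[Disorder], universe: Iterable[str] | None = None
    ) -> "CriteriaSet":
        """Build a set, deriving the universe (first-appearance order) if absent."""
        disorders = tuple(disorders)
        if universe is None:
            seen: dict[str, None] = {}
            for d in disorders:
                for v in expr_variables(d.expr):
                    seen.setdefault(v)
            universe = tuple(seen)
        return cls(disorders=disorders, universe=tuple(universe))

    def disorder(self, disorder_id: str) -> Disorder:
        for d in self.disorders:
            if d.id == disorder_id:
                return d
        raise KeyError(disorder_id)


# --------------------------------------------------------------------------
# File codec
# --------------------------------------------------------------------------
#
# Schema (YAML or JSON — JSON is a YAML subset):
#
#   characteristics: [label, ...]            # optional explicit universe
#   disorders:
#     - id: ndph
#       name: New daily persistent headache
#       probable: false
#       expr:
#         all:                               # {all: [...]}, {any: [...]},
#           - constant                       # {atleast: {k: 2, of: [...]}},
#           - more than 3 months             # or a bare label string (VAR)
#           ...

def expr_from_obj(obj: object, where: str = "expr") -> BoolExpr:
    """Decode the nested ``{all/any/atleast}`` schema into an AST."""
    if isinstance(obj, str):
        return Var(obj)
    if not isinstance(obj, dict) or len(obj) != 1:
        raise CriteriaError(
            f"{where}: expected a label or a single-key mapping "
            f"(all/any/atleast), got {obj!r}"
        )
    (op, args), = obj.items()
    if op == "all":
        return And(tuple(expr_from_obj(a, where) for a in _as_list(args, where, op)))
    if op == "any":
        return Or(tuple(expr_from_obj(a, where) for a in _as_list(args, where, op)))
    if op == "atleast":
        if not isinstance(args, dict) or set(args) != {"k", "of"}:
            raise CriteriaError(f"{where}: atleast requires keys 'k' and 'of'")
        of = _as_list(args["of"], where, "atleast.of")
        if any(not isinstance(x, str) for x in of):
            raise CriteriaError(f"{where}: atleast 'of' entries must be labels")
        return AtLeast(k=args["k"], children=tuple(Var(x) for x in of))
    raise CriteriaError(f"{where}: unknown operator {op!r}")


def _as_list(args: object, where: str, op: str) -> list:
    if not isinstance(args, list) or not args:
        raise CriteriaError(f"{where}: {op} requires a non-empty list")
    return args


def expr_to_obj(expr: BoolExpr) -> object:
    if isinstance(expr, Var):
        return expr.label
    if isinstance(expr, And):
        return {"all": [expr_to_obj(c) for c in expr.children]}
    if isinstance(expr, Or):
        return {"any": [expr_to_obj(c) for c in expr.children]}
    if isinstance(expr, AtLeast):
        return {"atleast": {"k": expr.k, "of": [c.label for c in expr.children]}}
    raise TypeError(f"not a BoolExpr node: {expr!r}")


def load_criteria(path: str | Path) -> CriteriaSet:
    """Load and validate a criteria file.

    Raises :class:`CriteriaError` naming the offending disorder on schema
    violations, and on references to characteristics outside a declared
    universe.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8-sig") as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise CriteriaError(f"{path}: top level must be a mapping")
    raw_disorders = doc.get("disorders", [])
    if raw_disorders is None:
        raw_disorders = []
    if not isinstance(raw_disorders, list):
        raise CriteriaError(f"{path}: 'disorders' must be a list")
    disorders = []
    for i, entry in enumerate(raw_disorders):
        if not isinstance(entry, dict) or "id" not in entry:
            raise CriteriaError(f"{path}: disorder #{i + 1} missing 'id'")
        did = entry["id"]
        try:
            disorders.append(
                Disorder(
                    id=str(did),
                    name=str(entry.get("name", did)),
                    probable=bool(entry.get("probable", False)),
                    expr=expr_from_obj(entry["expr"], where=f"disorder {did!r}"),
                )
            )
        except KeyError:
            raise CriteriaError(f"{path}: disorder {did!r} missing 'expr'") from None
        except CriteriaError as exc:
            raise CriteriaError(f"{path}: disorder {did!r}: {exc}") from None
    universe = doc.get("characteristics")
    try:
        if universe is None:
            return CriteriaSet.from_disorders(disorders)
        return CriteriaSet(disorders=tuple(disorders), universe=tuple(universe))
    except CriteriaError as exc:
        raise CriteriaError(f"{path}: {exc}") from None


def save_criteria(cs: CriteriaSet, path: str | Path) -> None:
    """Write a criteria set in the file schema (round-trips with load)."""
    doc = {
        "characteristics": list(cs.universe),
        "disorders": [
            {
                "id": d.id,
                "name": d.name,
                "probable": d.probable,
                "expr": expr_to_obj(d.expr),
            }
            for d in cs.disorders
        ],
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True, width=100)


# --------------------------------------------------------------------------
# Validation report
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Issue:
    level: str  # "ERROR" | "INFO"
    code: str
    message: str


def validate(cs: CriteriaSet) -> list[Issue]:
    """Pure structural report on a criteria set.

    Contradictory-pair inventory ("x" together with "no x") is reported as
    INFO, never as an error: the classification legitimately contains both
    (e.g. "photophobia" and "no photophobia" are distinct columns).
    """
    issues: list[Issue] = []
    ids = [d.id for d in cs.disorders]
    for dup in sorted({i for i in ids if ids.count(i) > 1}):
        issues.append(Issue("ERROR", "duplicate-id", f"duplicate disorder id {dup!r}"))
    used: set[str] = set()
    for d in cs.disorders:
        used.update(expr_variables(d.expr))
    for label in cs.universe:
        if label not in used:
            issues.append(
                Issue("INFO", "unused-characteristic",
                      f"characteristic {label!r} is referenced by no disorder")
            )
    universe = set(cs.universe)
    for label in sorted(universe):
        negated = f"no {label}"
        if negated in universe:
            issues.append(
                Issue(
                    "INFO",
                    "contradictory-pair",
                    f"both {label!r} and {negated!r} are characteristics "
                    f"(present/absent pair)",
                )
            )
    return issues
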