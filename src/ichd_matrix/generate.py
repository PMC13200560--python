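"""Random well-formed criteria sets for property testing.

The generator caps the number of distinct characteristics per disorder
so that exhaustive truth-table oracles over a disorder's variables stay
cheap (at most 2**max_vars evaluations).  Same seed, same output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .criteria import And, AtLeast, BoolExpr, CriteriaSet, Disorder, Or, Var

__all__ = ["GeneratorSpec", "random_criteria", "random_expr"]


@dataclass(frozen=True)
class GeneratorSpec:
    n_disorders: int = 5
    max_vars: int = 8  # distinct characteristics per disorder
    max_depth: int = 3
    and_weight: float = 1.0
    or_weight: float = 1.0
    atleast_probability: float = 0.25
    probable_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_disorders, self.max_vars, self.max_depth) < 1:
            raise ValueError("n_disorders, max_vars and max_depth must be positive")
        if self.and_weight <= 0 or self.or_weight <= 0:
            raise ValueError("operator weights must be positive")
        if not 0 <= self.atleast_probability <= 1:
            raise ValueError("atleast_probability must be in [0, 1]")


def random_expr(
    rng: random.Random, pool: list[str], spec: GeneratorSpec, depth: int = 0
) -> BoolExpr:
    """A random negation-free formula over ``pool``.

    At ``max_depth`` 1 the result is a single VAR or a flat AND/OR of
    VARs; ATLEAST nodes appear with ``atleast_probability`` and always
    have VAR children.
    """
    if depth >= spec.max_depth - 1 or (depth > 0 and rng.random() < 0.3):
        return Var(rng.choice(pool))
    if rng.random() < spec.atleast_probability and len(pool) >= 2:
        n = rng.randint(2, min(len(pool), 5))
        labels = rng.sample(pool, n)
        return AtLeast(k=rng.randint(1, n), children=tuple(Var(l) for l in labels))
    op = rng.choices(
        [And, Or], weights=[spec.and_weight, spec.or_weight], k=1
    )[0]
    n_children = rng.randint(1 if depth else 2, 4)
    children = tuple(
        random_expr(rng, pool, spec, depth + 1) for _ in range(n_children)
    )
    return op(children)


def random_criteria(spec: GeneratorSpec) -> CriteriaSet:
    """A well-formed random criteria set; deterministic in ``spec.seed``."""
    rng = random.Random(spec.seed)
    universe = [f"char {i:02d}" for i in range(1, spec.max_vars * 2 + 1)]
    disorders = []
    for d in range(spec.n_disorders):
        pool_size = rng.randint(1, spec.max_vars)
        pool = rng.sample(universe, pool_size)
        # letter suffix: row labels append a numeric phenotype index, so a
        # disorder id must not end in a digit
        suffix = ""
        k = d
        while True:
            suffix = chr(ord("a") + k % 26) + suffix
            k = k // 26 - 1
            if k < 0:
                break
        disorders.append(
            Disorder(
                id=f"disorder{suffix}",
                name=f"Synthetic disorder {d + 1}",
                probable=rng.random() < spec.probable_probability,
                expr=random_expr(rng, pool, spec),
            )
        )
    return CriteriaSet.from_disorders(disorders, universe=universe)
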