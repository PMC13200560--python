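"""Bundled reference instance and loaders.

The package ships a reviewed hand-encoding of the ICHD-3 primary
headache criteria (``data/ichd3_primary.yaml``); the matrix built from
it is the reference instance used throughout the examples and tests.
The original article's supplementary matrix CSV is not redistributable
with this package; :func:`load_supplementary_matrix` reads a
user-supplied copy for reconciliation against the bundled encoding.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

from .criteria import CriteriaSet, load_criteria
from .matrix import BiadjacencyMatrix, build_matrix, read_matrix_csv

__all__ = [
    "bundled_criteria_path",
    "bundled_criteria",
    "bundled_matrix",
    "load_supplementary_matrix",
]


def bundled_criteria_path() -> Path:
    return Path(str(resources.files("ichd_matrix") / "data" / "ichd3_primary.yaml"))


@lru_cache(maxsize=1)
def bundled_criteria() -> CriteriaSet:
    """The bundled ICHD-3 primary headache criteria encoding."""
    return load_criteria(bundled_criteria_path())


@lru_cache(maxsize=1)
def bundled_matrix() -> BiadjacencyMatrix:
    """The phenotype × characteristic matrix of the bundled encoding."""
    return build_matrix(bundled_criteria())


def load_supplementary_matrix(path: str | Path | None = None) -> BiadjacencyMatrix:
    """Load an externally obtained copy of the published supplementary
    matrix CSV ("data sheet 7.csv" of the source article).

    The file is not bundled; obtain it from the article's supplementary
    material and pass its path (or place it at ``data sheet 7.csv`` in
    the working directory).
    """
    candidates = [Path(path)] if path is not None else [
        Path("data sheet 7.csv"),
        Path("datasheet7.csv"),
    ]
    for candidate in candidates:
        if candidate.exists():
            return read_matrix_csv(candidate)
    raise FileNotFoundError(
        "supplementary matrix CSV not found; download 'data sheet 7.csv' from "
        "the source article's supplementary material and pass its path"
    )
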