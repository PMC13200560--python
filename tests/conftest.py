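import numpy as np
import pytest

from ichd_matrix import (
    And,
    AtLeast,
    BiadjacencyMatrix,
    CriteriaSet,
    Disorder,
    Or,
    Var,
    bundled_criteria,
    bundled_matrix,
)


@pytest.fixture(scope="session")
def ndph_expr():
    """NDPH: a pure conjunction of four characteristics."""
    return And(
        (
            Var("clearly remembered onset"),
            Var("constant"),
            Var("more than 3 months"),
            Var("unremitting within 24 h"),
        )
    )


@pytest.fixture(scope="session")
def migraine_wo_aura_expr():
    """Migraine without aura: >=5 attacks, 4-72 h, at least two of four
    pain characteristics, and nausea/vomiting or (photophobia and
    phonophobia)."""
    return And(
        (
            Var("greater than 5 episodes"),
            Var("4 to 72 h"),
            AtLeast(
                2,
                (
                    Var("unilateral"),
                    Var("pulsating"),
                    Var("moderate to severe"),
                    Var("aggravated by physical activity"),
                ),
            ),
            Or((Var("nausea/vomiting"), And((Var("photophobia"), Var("phonophobia"))))),
        )
    )


@pytest.fixture(scope="session")
def ndph_disorder(ndph_expr):
    return Disorder(id="ndph", name="New daily persistent headache", expr=ndph_expr)


@pytest.fixture(scope="session")
def ndph_criteria(ndph_disorder):
    return CriteriaSet.from_disorders([ndph_disorder])


@pytest.fixture(scope="session")
def toy_matrix():
    """A tiny labelled matrix: two phenotypes over three characteristics."""
    return BiadjacencyMatrix(
        row_labels=("a1", "b1"),
        col_labels=("x", "y", "z"),
        values=np.array([[1, 1, 0], [1, 0, 1]], dtype=np.uint8),
    )


@pytest.fixture(scope="session")
def reference_criteria():
    return bundled_criteria()


@pytest.fixture(scope="session")
def reference_matrix():
    return bundled_matrix()
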