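import itertools

import numpy as np
import pytest

from ichd_matrix import (
    ResponseVector,
    UnknownCharacteristicError,
    build_matrix,
    contradiction_check,
    diagnose,
    evaluate,
)
from ichd_matrix.generate import GeneratorSpec, random_criteria
from ichd_matrix.matrix import BiadjacencyMatrix, row_sums


class TestExamples:
    def test_exact_ndph_responses_diagnose_ndph(self, ndph_criteria, ndph_expr):
        m = build_matrix(ndph_criteria)
        answers = {label: 1 for label in m.col_labels}
        result = diagnose(m, ResponseVector(answers))
        assert result.satisfied_phenotypes == ("ndph1",)
        assert result.diagnosed_disorders == ("ndph",)
        # cross-check against direct Boolean evaluation of the criteria
        assert evaluate(ndph_expr, set(m.col_labels))

    def test_all_zeros_matches_nothing(self, reference_matrix):
        result = diagnose(reference_matrix, ResponseVector({}))
        assert result.satisfied_phenotypes == ()
        assert result.diagnosed_disorders == ()

    def test_all_ones_matches_everything(self, reference_matrix):
        answers = {label: 1 for label in reference_matrix.col_labels}
        result = diagnose(reference_matrix, ResponseVector(answers))
        assert result.satisfied_phenotypes == reference_matrix.row_labels

    def test_unknown_characteristic_listed(self, reference_matrix):
        v = ResponseVector({"photophobia": 1, "not a real finding": 1})
        with pytest.raises(UnknownCharacteristicError, match="not a real finding"):
            diagnose(reference_matrix, v)

    def test_match_score_reflects_partial_matches(self, ndph_criteria):
        m = build_matrix(ndph_criteria)
        three_of_four = dict.fromkeys(list(m.col_labels)[:3], 1)
        result = diagnose(m, ResponseVector(three_of_four))
        assert result.satisfied_phenotypes == ()
        assert result.scores["ndph1"] == pytest.approx(0.75)


class TestContradictionCheck:
    def test_both_polarities_present_warns(self):
        v = ResponseVector({"photophobia": 1, "no photophobia": 1})
        warnings = contradiction_check(None, v)
        assert len(warnings) == 1
        assert "photophobia" in warnings[0]

    def test_single_polarity_is_silent(self):
        assert contradiction_check(None, ResponseVector({"photophobia": 1})) == []

    def test_empty_vector_is_silent(self):
        assert contradiction_check(None, ResponseVector({})) == []

    def test_never_blocks_diagnosis(self, reference_matrix):
        answers = {label: 1 for label in reference_matrix.col_labels}
        v = ResponseVector(answers)
        assert contradiction_check(reference_matrix, v)  # many pairs flagged
        assert diagnose(reference_matrix, v).diagnosed_disorders  # still diagnoses


class TestRowSumTheorem:
    """The row-sum matching rule is equivalent to direct Boolean
    evaluation of each disorder's criteria formula."""

    @pytest.mark.parametrize("seed", range(6))
    def test_exhaustive_equivalence_on_random_criteria(self, seed):
        spec = GeneratorSpec(seed=seed, n_disorders=4, max_vars=6, max_depth=3,
                             atleast_probability=0.3)
        cs = random_criteria(spec)
        m = build_matrix(cs)
        n = len(cs.universe)
        assert n <= 15
        sums = row_sums(m)
        mat = m.values.astype(np.int64)
        for bits in itertools.product((0, 1), repeat=n):
            v = np.array(bits, dtype=np.int64)
            satisfied_rows = (mat @ v) == sums
            matrix_diagnoses = {
                label.rstrip("0123456789")
                for label, sat in zip(m.row_labels, satisfied_rows)
                if sat
            }
            present = {c for c, b in zip(m.col_labels, bits) if b}
            direct = {d.id for d in cs.disorders if evaluate(d.expr, present)}
            assert matrix_diagnoses == direct

    @pytest.mark.parametrize("seed", range(3))
    def test_api_path_agrees_with_direct_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        cs = random_criteria(GeneratorSpec(seed=seed + 50, n_disorders=5, max_vars=7))
        m = build_matrix(cs)
        for _ in range(100):
            bits = rng.integers(0, 2, size=len(m.col_labels))
            answers = dict(zip(m.col_labels, (int(b) for b in bits)))
            result = diagnose(m, ResponseVector(answers))
            present = {c for c, b in answers.items() if b}
            direct = {d.id for d in cs.disorders if evaluate(d.expr, present)}
            assert set(result.diagnosed_disorders) == direct

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_in_added_characteristics(self, seed):
        rng = np.random.default_rng(seed + 99)
        cs = random_criteria(GeneratorSpec(seed=seed, n_disorders=4, max_vars=6))
        m = build_matrix(cs)
        for _ in range(50):
            bits = rng.integers(0, 2, size=len(m.col_labels))
            answers = dict(zip(m.col_labels, (int(b) for b in bits)))
            before = set(diagnose(m, ResponseVector(answers)).diagnosed_disorders)
            grown = dict(answers)
            for label in rng.choice(m.col_labels, size=3):
                grown[label] = 1
            after = set(diagnose(m, ResponseVector(grown)).diagnosed_disorders)
            assert before <= after

    def test_invariant_under_matrix_permutation(self, reference_matrix):
        rng = np.random.default_rng(7)
        m = reference_matrix
        perm_r = rng.permutation(m.shape[0])
        perm_c = rng.permutation(m.shape[1])
        permuted = BiadjacencyMatrix(
            tuple(m.row_labels[i] for i in perm_r),
            tuple(m.col_labels[j] for j in perm_c),
            m.values[np.ix_(perm_r, perm_c)],
        )
        answers = {label: 1 for label in m.col_labels if "aura" in label}
        answers["fully reversible"] = 1
        answers["greater than 2 episodes"] = 1
        base = diagnose(m, ResponseVector(answers))
        perm = diagnose(permuted, ResponseVector(answers))
        assert set(base.satisfied_phenotypes) == set(perm.satisfied_phenotypes)
        assert set(base.diagnosed_disorders) == set(perm.diagnosed_disorders)
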