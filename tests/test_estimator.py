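"""Point estimators: crude, transition matrix, equilibrium, degree weighting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdskit import (
    TraitPartition,
    build_recruitment_forest,
    crude_proportion,
    equilibrium_distribution,
    estimate_transition_matrix,
    harmonic_mean_degrees,
    prevalence_ratio,
    rds_adjusted_proportion,
    wald_test,
)
from rdskit.errors import (
    DegenerateChainError,
    InsufficientDataError,
    UndefinedRatioError,
    UndefinedTestError,
)
from rdskit.estimator import DegreeSummary, TransitionMatrix, transition_matrix_from_counts

from conftest import make_record


def _partition(records):
    return TraitPartition.from_binary_trait(records, "drug:lifetime")


class TestCrude:
    def test_pooled_sample_fraction(self):
        """277 users in a sample of 1115 is a crude prevalence of 24.84%."""
        recs = _sample_of(1115, 277)
        est = crude_proportion(recs, _partition(recs))
        assert est["user"].proportion == pytest.approx(277 / 1115)
        assert round(est["user"].proportion, 4) == 0.2484
        assert est["user"].proportion + est["non-user"].proportion == pytest.approx(1.0)

    def test_all_one_group(self):
        recs = _sample_of(10, 10)
        assert crude_proportion(recs, _partition(recs))["user"].proportion == 1.0

    def test_even_split(self):
        recs = _sample_of(100, 50)
        assert crude_proportion(recs, _partition(recs))["user"].proportion == 0.5

    def test_empty_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            crude_proportion([], TraitPartition("t", ("a", "b"), {}))


def _sample_of(n: int, n_users: int):
    """n isolated seeds, the first n_users trait-positive (codes all unique)."""
    recs = []
    for i in range(n):
        label = f"{chr(ord('A') + i // 1000)}{i % 1000:03d}"
        recs.append(
            make_record(f"p{i:04d}", f"{label}-0000000000", trait=int(i < n_users))
        )
    return recs


class TestTransitionMatrix:
    def test_hand_counted_probabilities(self, two_group_forest):
        forest = build_recruitment_forest(two_group_forest)
        T = estimate_transition_matrix(forest, _partition(two_group_forest))
        assert T.groups == ("user", "non-user")
        np.testing.assert_array_equal(T.counts, [[1, 2], [1, 0]])
        np.testing.assert_allclose(T.S, [[1 / 3, 2 / 3], [1, 0]])

    def test_assortative_edges_give_identity(self):
        recs = [
            make_record("s1", "F001-0000000000", trait=1),
            make_record("a", "F001-1000000000", trait=1),
            make_record("s2", "F002-0000000000", trait=0),
            make_record("b", "F002-1000000000", trait=0),
        ]
        T = estimate_transition_matrix(build_recruitment_forest(recs), _partition(recs))
        np.testing.assert_array_equal(T.S, np.eye(2))

    def test_zero_row_uniform_policy(self):
        recs = [
            make_record("s", "F001-0000000000", trait=0),
            make_record("a", "F001-1000000000", trait=1),
        ]
        T = estimate_transition_matrix(build_recruitment_forest(recs), _partition(recs))
        np.testing.assert_allclose(T.S[0], [0.5, 0.5])  # no user ever recruited
        assert T.zero_rows == ["user"]

    def test_zero_row_self_loop_policy(self):
        recs = [
            make_record("s", "F001-0000000000", trait=0),
            make_record("a", "F001-1000000000", trait=1),
        ]
        T = estimate_transition_matrix(
            build_recruitment_forest(recs), _partition(recs), zero_row_policy="self_loop"
        )
        np.testing.assert_allclose(T.S[0], [1.0, 0.0])

    def test_reciprocity_smoothing_symmetrises_counts(self):
        T = transition_matrix_from_counts(
            np.array([[0.0, 4.0], [2.0, 2.0]]), ("a", "b"), smoothing=True
        )
        # smoothed counts [[0,3],[3,2]] -> rows [[0,1],[0.6,0.4]]
        np.testing.assert_allclose(T.S, [[0.0, 1.0], [0.6, 0.4]])

    def test_no_edges_is_insufficient(self):
        recs = [make_record("s", "F001-0000000000", trait=1),
                make_record("t", "F002-0000000000", trait=0)]
        with pytest.raises(InsufficientDataError):
            estimate_transition_matrix(build_recruitment_forest(recs), _partition(recs))

    def test_rows_are_stochastic(self, simulated_survey):
        _, _, records, forest = simulated_survey
        T = estimate_transition_matrix(forest, _partition(records))
        np.testing.assert_allclose(T.S.sum(axis=1), 1.0, atol=1e-12)


class TestEquilibrium:
    def test_symmetric_chain(self):
        T = TransitionMatrix(("a", "b"), np.full((2, 2), 0.5), np.zeros((2, 2)))
        np.testing.assert_allclose(equilibrium_distribution(T), [0.5, 0.5])

    def test_hand_solved_two_state_chain(self):
        T = TransitionMatrix(
            ("a", "b"), np.array([[2 / 3, 1 / 3], [1.0, 0.0]]), np.zeros((2, 2))
        )
        np.testing.assert_allclose(equilibrium_distribution(T), [0.75, 0.25])

    def test_identity_matrix_is_degenerate(self):
        T = TransitionMatrix(("a", "b"), np.eye(2), np.zeros((2, 2)))
        with pytest.raises(DegenerateChainError) as err:
            equilibrium_distribution(T)
        assert sorted(map(tuple, err.value.absorbing_classes)) == [("a",), ("b",)]

    def test_stationarity_residual_small(self, simulated_survey):
        _, _, records, forest = simulated_survey
        T = estimate_transition_matrix(forest, _partition(records))
        pi = equilibrium_distribution(T)
        assert np.max(np.abs(pi @ T.S - pi)) < 1e-10


class TestDegrees:
    def test_constant_degrees(self):
        recs = [make_record(f"p{i}", f"A{i:03d}-0000000000", degree=2, trait=i % 2)
                for i in range(4)]
        ds = harmonic_mean_degrees(recs, _partition(recs))
        assert ds.harmonic_mean == {"user": 2.0, "non-user": 2.0}

    def test_harmonic_mean_by_hand(self):
        recs = [
            make_record("a", "A000-0000000000", degree=1, trait=1),
            make_record("b", "A001-0000000000", degree=4, trait=1),
            make_record("c", "A002-0000000000", degree=3, trait=0),
        ]
        ds = harmonic_mean_degrees(recs, _partition(recs))
        assert ds.harmonic_mean["user"] == pytest.approx(2 / (1 + 0.25))

    def test_invalid_degree_excluded_and_counted(self):
        recs = [
            make_record("a", "A000-0000000000", degree=3, trait=1),
            make_record("b", "A001-0000000000", degree=0, trait=1),
            make_record("c", "A002-0000000000", degree=2, trait=0),
        ]
        ds = harmonic_mean_degrees(recs, _partition(recs))
        assert ds.harmonic_mean["user"] == 3.0
        assert ds.n_excluded["user"] == 1

    def test_group_without_valid_degrees(self):
        recs = [
            make_record("a", "A000-0000000000", degree=0, trait=1),
            make_record("c", "A002-0000000000", degree=2, trait=0),
        ]
        with pytest.raises(InsufficientDataError):
            harmonic_mean_degrees(recs, _partition(recs))

    def test_bounded_by_observed_degrees(self, simulated_survey):
        _, _, records, _ = simulated_survey
        part = _partition(records)
        ds = harmonic_mean_degrees(records, part)
        for g in part.groups:
            degs = [r.degree for r in records if part.group_of(r.pid) == g]
            assert min(degs) <= ds.harmonic_mean[g] <= max(degs)


class TestRdsAdjusted:
    def test_equal_degrees_leave_equilibrium_unchanged(self):
        T = TransitionMatrix(
            ("a", "b"), np.array([[2 / 3, 1 / 3], [1.0, 0.0]]), np.zeros((2, 2))
        )
        ds = DegreeSummary(("a", "b"), {"a": 2.0, "b": 2.0}, {"a": 5, "b": 5},
                           {"a": 0, "b": 0})
        est = rds_adjusted_proportion(T, ds)
        assert est["a"].proportion == pytest.approx(0.75)

    def test_two_group_closed_form_example(self):
        T = TransitionMatrix(
            ("a", "b"), np.array([[0.5, 0.5], [0.5, 0.5]]), np.zeros((2, 2))
        )
        ds = DegreeSummary(("a", "b"), {"a": 4.0, "b": 1.0}, {"a": 5, "b": 5},
                           {"a": 0, "b": 0})
        est = rds_adjusted_proportion(T, ds)
        assert est["a"].proportion == pytest.approx(0.5 * 1.0 / (0.5 * 4.0 + 0.5 * 1.0))

    @settings(derandomize=True, max_examples=200)
    @given(
        sab=st.floats(0.01, 0.99),
        sba=st.floats(0.01, 0.99),
        da=st.floats(1.0, 50.0),
        db=st.floats(1.0, 50.0),
    )
    def test_matches_closed_form_for_two_groups(self, sab, sba, da, db):
        """The multi-group formula reduces exactly to the two-group identity."""
        T = TransitionMatrix(
            ("a", "b"),
            np.array([[1 - sab, sab], [sba, 1 - sba]]),
            np.zeros((2, 2)),
        )
        ds = DegreeSummary(("a", "b"), {"a": da, "b": db}, {"a": 1, "b": 1},
                           {"a": 0, "b": 0})
        got = rds_adjusted_proportion(T, ds)["a"].proportion
        want = sba * db / (sab * da + sba * db)
        assert got == pytest.approx(want, abs=1e-12)


class TestContrasts:
    def test_wald_null(self):
        res = wald_test(0.3, 0.05, 0.3, 0.05)
        assert res.z == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_wald_known_value(self):
        res = wald_test(0.3, 0.05, 0.1, 0.05)
        assert res.z == pytest.approx(2.828, abs=1e-3)
        assert res.p_value == pytest.approx(0.00468, abs=1e-4)

    def test_wald_antisymmetric(self):
        a = wald_test(0.3, 0.05, 0.1, 0.04)
        b = wald_test(0.1, 0.04, 0.3, 0.05)
        assert a.z == pytest.approx(-b.z)
        assert a.p_value == pytest.approx(b.p_value)

    def test_wald_zero_se_undefined(self):
        with pytest.raises(UndefinedTestError):
            wald_test(0.3, 0.0, 0.1, 0.05)

    @pytest.mark.parametrize(
        "early, late, expected",
        [
            (16.3, 5.7, 2.9),
            (10.2, 2.7, 3.8),
            (6.1, 2.0, 3.1),   # half-away-from-zero at the midpoint
            (4.9, 2.0, 2.5),
            (5.0, 5.0, 1.0),
        ],
    )
    def test_prevalence_ratio_printed_rounding(self, early, late, expected):
        assert prevalence_ratio(early, late) == expected

    def test_ratio_zero_denominator(self):
        with pytest.raises(UndefinedRatioError):
            prevalence_ratio(5.0, 0.0)
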