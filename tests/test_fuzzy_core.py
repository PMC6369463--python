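import numpy as np
import pytest

import _oracle
from rumselect.data_model import DecisionTable, ValidationError
from rumselect.fuzzy_core import (
    granule_decision_counts,
    granules,
    granules_universe,
    rough_decision,
    similarity_matrix,
    soft_card_leq,
)


def table_from_values(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    order = list(dict.fromkeys(labels))
    return DecisionTable(
        values=values,
        labels=labels,
        attribute_ids=[f"a{j}" for j in range(values.shape[1])],
        class_ids=order,
        normalized=True,
    )


class TestSimilarityMatrix:
    def test_single_attribute_values(self):
        # |x−y| = 0.3 at alpha 0.1 keeps 0.7; |x−y| = 0.95 is cut to 0
        t = table_from_values([[0.0], [0.3], [0.95]], ["a", "b", "a"])
        sim = similarity_matrix(t, ["a0"], alpha=0.1)
        assert sim.values[0, 1] == pytest.approx(0.7)
        assert sim.values[0, 2] == 0.0

    def test_min_aggregation_over_attributes(self):
        t = table_from_values([[0.0, 0.0], [0.3, 0.6]], ["a", "b"])
        sim = similarity_matrix(t, ["a0", "a1"], alpha=0.0)
        assert sim.values[0, 1] == pytest.approx(0.4)

    def test_boundary_distance_exactly_one_minus_alpha_kept(self):
        # dyadic values so the boundary comparison is float-exact
        t = table_from_values([[0.0], [0.75]], ["a", "b"])
        sim = similarity_matrix(t, ["a0"], alpha=0.25)
        assert sim.values[0, 1] == pytest.approx(0.25)

    def test_reflexive_symmetric_on_random_tables(self, make_random_table):
        rng = np.random.default_rng(3)
        for _ in range(10):
            t = make_random_table(rng, 12, 3)
            sim = similarity_matrix(t, t.attribute_ids, alpha=rng.uniform(0, 0.6))
            np.testing.assert_array_equal(np.diag(sim.values), 1.0)
            np.testing.assert_allclose(sim.values, sim.values.T)
            off = sim.values[~np.eye(12, dtype=bool)]
            assert np.all((off == 0) | (off >= sim.alpha))

    def test_matches_scalar_oracle(self, make_random_table):
        rng = np.random.default_rng(4)
        t = make_random_table(rng, 8, 3)
        sim = similarity_matrix(t, ["a0", "a2"], alpha=0.2)
        expected = _oracle.similarity(t.values.tolist(), [0, 2], 0.2)
        np.testing.assert_allclose(sim.values, expected)

    def test_empty_subset_rejected(self, make_random_table):
        t = make_random_table(np.random.default_rng(0), 5, 2)
        with pytest.raises(ValidationError, match="empty"):
            similarity_matrix(t, [], alpha=0.1)


class TestGranules:
    def test_example2_cardinalities(self, example2):
        sim, _ = example2
        g = granules(sim)
        np.testing.assert_array_equal(g.cardinalities, [3, 5, 5, 4, 4])
        np.testing.assert_array_equal(np.diag(g.granules), 1.0)

    def test_alpha_one_minus_epsilon_isolates_distinct_rows(self):
        t = table_from_values([[0.0], [0.5], [1.0]], ["a", "b", "a"])
        sim = similarity_matrix(t, ["a0"], alpha=0.99)
        g = granules(sim)
        np.testing.assert_array_equal(g.cardinalities, [1, 1, 1])

    def test_nesting_in_alpha(self, make_random_table):
        # larger radius → entrywise smaller granules → smaller cardinalities
        rng = np.random.default_rng(5)
        t = make_random_table(rng, 15, 4)
        g_lo = granules(similarity_matrix(t, t.attribute_ids, alpha=0.1))
        g_hi = granules(similarity_matrix(t, t.attribute_ids, alpha=0.4))
        assert np.all(g_hi.granules <= g_lo.granules + 1e-12)
        assert np.all(g_hi.cardinalities <= g_lo.cardinalities)

    def test_universe_granules(self):
        g = granules_universe(4)
        np.testing.assert_array_equal(g.granules, 1.0)
        np.testing.assert_array_equal(g.cardinalities, 4)


class TestRoughDecision:
    def test_example2_matrix_to_four_decimals(self, example2):
        sim, labels = example2
        rd = rough_decision(sim, labels)
        expected = np.array(
            [
                [1.0000, 0.0000],
                [0.7311, 0.2689],
                [0.7973, 0.2027],
                [0.1542, 0.8458],
                [0.3972, 0.6028],
            ]
        )
        np.testing.assert_allclose(np.round(rd.values, 4), expected)

    def test_identity_similarity_gives_one_hot(self):
        from rumselect.fuzzy_core import SimilarityMatrix

        labels = np.array(["a", "b", "a"], dtype=object)
        sim = SimilarityMatrix(np.eye(3), ("a0",), 0.0)
        rd = rough_decision(sim, labels)
        np.testing.assert_array_equal(rd.values, [[1, 0], [0, 1], [1, 0]])

    def test_rows_sum_to_one_on_random_tables(self, make_random_table):
        rng = np.random.default_rng(6)
        for _ in range(20):
            t = make_random_table(rng, 10, 3, n_classes=rng.integers(2, 4))
            sim = similarity_matrix(t, t.attribute_ids, alpha=rng.uniform(0, 0.5))
            rd = rough_decision(sim, t.labels)
            np.testing.assert_allclose(rd.values.sum(axis=1), 1.0, atol=1e-9)
            assert rd.values.min() >= 0 and rd.values.max() <= 1


class TestSoftCardinality:
    def test_example1_both_directions(self, example1_vectors):
        S, T = example1_vectors
        assert soft_card_leq(S, T) == 4
        assert soft_card_leq(T, S) == 8

    def test_self_count_is_nonzero_support(self):
        S = np.array([0.5, 0.0, 0.2, 1.0])
        assert soft_card_leq(S, S) == 3  # every tie counts, zeros never do

    def test_all_zero_vector(self):
        S = np.zeros(6)
        T = np.ones(6)
        assert soft_card_leq(S, T) == 0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            soft_card_leq(np.ones(3), np.ones(4))


class TestGranuleDecisionCounts:
    def test_example2_counts(self, example2):
        sim, labels = example2
        g = granules(sim)
        rd = rough_decision(sim, labels)
        counts = granule_decision_counts(g, rd, labels)
        np.testing.assert_array_equal(counts, [3, 2, 3, 2, 1])

    def test_matches_per_sample_soft_counts(self, make_random_table):
        rng = np.random.default_rng(7)
        t = make_random_table(rng, 9, 2)
        sim = similarity_matrix(t, t.attribute_ids, alpha=0.2)
        g = granules(sim)
        rd = rough_decision(sim, t.labels)
        counts = granule_decision_counts(g, rd, t.labels)
        for i in range(t.n_samples):
            own = rd.class_ids.index(t.labels[i])
            assert counts[i] == soft_card_leq(g.granules[i], rd.values[:, own])
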