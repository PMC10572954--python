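"""Adapted majority voting, tie-breaking, and the combination search."""

import numpy as np
import pytest

from osteovote import (EnsembleCombination, ProbabilityMatrix,
                       adapted_majority_vote, brute_force_search,
                       enumerate_combinations, generate_prediction_matrices,
                       tally_votes)


def pm(learner_id: str, rows) -> ProbabilityMatrix:
    return ProbabilityMatrix(learner_id=learner_id, values=np.asarray(rows, dtype=float))


def reference_vote(predictions):
    """Independent count-then-resolve reference for the voting rule."""
    n, k = predictions[0].values.shape
    labels = np.empty(n, dtype=int)
    for i in range(n):
        votes = [0] * k
        for p in predictions:
            votes[int(np.argmax(p.values[i]))] += 1
        top = max(votes)
        tied = [c for c in range(k) if votes[c] == top]
        if len(tied) == 1:
            labels[i] = tied[0]
        else:
            sums = {c: sum(float(p.values[i, c]) for p in predictions) for c in tied}
            best = max(sums.values())
            labels[i] = min(c for c in tied if sums[c] == best)
    return labels


class TestProbabilityMatrix:
    def test_row_sum_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pm("a", [[0.5, 0.4]])

    def test_range_enforced(self):
        with pytest.raises(ValueError):
            pm("a", [[1.2, -0.2]])


class TestTallyVotes:
    def test_direct_count(self):
        mats = [pm("a", [[0.6, 0.3, 0.1]]),
                pm("b", [[0.2, 0.7, 0.1]]),
                pm("c", [[0.1, 0.8, 0.1]])]
        np.testing.assert_array_equal(tally_votes(mats).counts, [[1, 2, 0]])

    def test_unanimous(self):
        mats = [pm(i, [[0.1, 0.1, 0.8]]) for i in "abc"]
        np.testing.assert_array_equal(tally_votes(mats).counts, [[0, 0, 3]])

    def test_learner_order_irrelevant(self):
        rng = np.random.default_rng(0)
        rows = rng.dirichlet(np.ones(3), size=(4, 20))
        mats = [pm(f"l{i}", rows[i]) for i in range(4)]
        a = tally_votes(mats).counts
        b = tally_votes(mats[::-1]).counts
        np.testing.assert_array_equal(a, b)

    def test_requires_two_learners(self):
        with pytest.raises(ValueError):
            tally_votes([pm("a", [[0.5, 0.5]])])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            tally_votes([pm("a", [[0.5, 0.5]]), pm("b", [[0.3, 0.3, 0.4]])])


class TestAdaptedMajorityVote:
    def test_strict_majority_wins(self):
        mats = [pm("a", [[0.6, 0.3, 0.1]]),
                pm("b", [[0.2, 0.7, 0.1]]),
                pm("c", [[0.1, 0.8, 0.1]])]
        labels, ties = adapted_majority_vote(mats)
        assert labels.tolist() == [1]
        assert not ties[0]

    def test_three_way_tie_resolved_by_summed_probability(self):
        mats = [pm("a", [[0.8, 0.1, 0.1]]),
                pm("b", [[0.2, 0.5, 0.3]]),
                pm("c", [[0.3, 0.3, 0.4]])]
        labels, ties = adapted_majority_vote(mats)
        # votes 1/1/1; summed probabilities (1.3, 0.9, 0.8) -> class 0
        assert labels.tolist() == [0]
        assert ties[0]

    def test_identical_learners_reduce_to_argmax(self):
        rng = np.random.default_rng(1)
        rows = rng.dirichlet(np.ones(4), size=30)
        mats = [pm(f"l{i}", rows) for i in range(3)]
        labels, ties = adapted_majority_vote(mats)
        np.testing.assert_array_equal(labels, rows.argmax(axis=1))
        assert not ties.any()

    def test_residual_exact_tie_prefers_lowest_index(self):
        mats = [pm("a", [[0.5, 0.3, 0.2]]), pm("b", [[0.3, 0.5, 0.2]])]
        labels, ties = adapted_majority_vote(mats)
        # votes 1/1/0, summed probabilities 0.8/0.8 exactly
        assert labels.tolist() == [0]
        assert ties[0]

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_on_random_instances(self, seed):
        """100 random instances per seed against the count-then-resolve reference."""
        rng = np.random.default_rng(seed)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            m = int(rng.integers(2, 7))
            n = int(rng.integers(1, 8))
            # quantized rows make vote and probability ties common
            raw = rng.integers(1, 5, size=(m, n, k)).astype(float)
            rows = raw / raw.sum(axis=2, keepdims=True)
            mats = [pm(f"l{i}", rows[i]) for i in range(m)]
            labels, _ = adapted_majority_vote(mats)
            np.testing.assert_array_equal(labels, reference_vote(mats))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        rows = rng.dirichlet(np.ones(3), size=(5, 50))
        mats = [pm(f"l{i}", rows[i]) for i in range(5)]
        a, _ = adapted_majority_vote(mats)
        b, _ = adapted_majority_vote(mats[::-1])
        np.testing.assert_array_equal(a, b)

    def test_strict_majority_immune_to_probabilities(self):
        """Probabilities cannot override a strict vote majority."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            k = 3
            votes = [0, 0, 1, 1, 1]  # class 1 holds a strict majority
            rows = []
            for v in votes:
                row = rng.dirichlet(np.ones(k))
                top = row.argmax()
                row[[v, top]] = row[[top, v]]
                rows.append(row)
            mats = [pm(f"l{i}", [r]) for i, r in enumerate(rows)]
            labels, _ = adapted_majority_vote(mats)
            assert labels[0] == 1

    def test_condorcet_improvement_over_mean_learner(self):
        """Independent 0.8-accuracy learners: the ensemble is no worse than
        the mean single learner (within 3 standard errors), K=3, n=2000."""
        n = 2000
        rng = np.random.default_rng(5)
        y = rng.integers(0, 3, n)
        mats = generate_prediction_matrices(3, y, 3, [0.8, 0.8, 0.8], seed=55)
        single = np.mean([(m.argmax_labels() == y).mean() for m in mats])
        labels, _ = adapted_majority_vote(mats)
        ens = (labels == y).mean()
        se = np.sqrt(0.8 * 0.2 / n)
        assert ens >= single - 3 * se


class TestEnumerateCombinations:
    @pytest.mark.parametrize("k,expected", [(2, 1), (3, 4), (5, 26)])
    def test_counts(self, k, expected):
        ids = [f"l{i}" for i in range(k)]
        combos = enumerate_combinations(ids)
        assert len(combos) == expected == 2**k - k - 1

    def test_k3_members(self):
        combos = enumerate_combinations(["A", "B", "C"])
        assert [c.learner_ids for c in combos] == [
            ("A", "B"), ("A", "C"), ("B", "C"), ("A", "B", "C")]

    def test_deterministic_order(self):
        assert enumerate_combinations(["b", "a", "c"]) == enumerate_combinations(["c", "b", "a"])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            enumerate_combinations(["only"])

    def test_combination_validates_size(self):
        with pytest.raises(ValueError):
            EnsembleCombination(("solo",))


class TestBruteForceSearch:
    def test_adversarial_member_excluded(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 3, 40)
        perfect = np.eye(3)[y] * 0.94 + 0.02
        wrong = np.eye(3)[(y + 1) % 3] * 0.94 + 0.02
        mats = [pm("A", perfect), pm("B", perfect), pm("C", wrong)]
        result = brute_force_search(mats, y)
        assert result.selected.learner_ids == ("A", "B")
        assert result.best_report.accuracy == 1.0

    def test_all_perfect_selects_smallest_then_lexicographic(self):
        y = np.array([0, 1, 2] * 5)
        perfect = np.eye(3)[y] * 0.94 + 0.02
        mats = [pm(lid, perfect) for lid in ("B", "A", "C")]
        result = brute_force_search(mats, y)
        assert result.selected.learner_ids == ("A", "B")
        assert all(r.accuracy == 1.0 for _, r in result.ranked)

    def test_ranking_matches_exhaustive_reevaluation(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 3, 60)
        mats = generate_prediction_matrices(4, y, 3, [0.9, 0.75, 0.6, 0.5], seed=77)
        result = brute_force_search(mats, y)
        assert len(result.ranked) == 2**4 - 4 - 1
        by_id = {m.learner_id: m for m in mats}
        for combo, rep in result.ranked:
            labels = reference_vote([by_id[l] for l in combo.learner_ids])
            assert rep.accuracy == pytest.approx((labels == y).mean())
        accs = [r.accuracy for _, r in result.ranked]
        assert accs == sorted(accs, reverse=True)

    def test_unknown_criterion_rejected(self):
        y = np.array([0, 1])
        mats = [pm("a", [[0.9, 0.1], [0.1, 0.9]]), pm("b", [[0.8, 0.2], [0.2, 0.8]])]
        with pytest.raises(ValueError, match="criterion"):
            brute_force_search(mats, y, criterion="vibes")

    def test_label_alignment_enforced(self):
        mats = [pm("a", [[0.9, 0.1]]), pm("b", [[0.8, 0.2]])]
        with pytest.raises(ValueError, match="align"):
            brute_force_search(mats, [0, 1], criterion="accuracy")
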