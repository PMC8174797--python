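"""State estimation: k-means, majority-rule selection, assignment, matching."""

import itertools

import numpy as np
import pytest
from scipy import stats

import dfcstates as d
from dfcstates.cluster import DEFAULT_INDEX_SET


@pytest.fixture(scope="module")
def two_clouds():
    rng = np.random.default_rng(0)
    a = rng.normal(loc=0.0, scale=0.1, size=(100, 45))
    b = rng.normal(loc=2.0, scale=0.1, size=(80, 45))
    return np.vstack([a, b]), a.mean(axis=0), b.mean(axis=0)


class TestKMeans:
    def test_separable_clouds_recover_means(self, two_clouds):
        x, mean_a, mean_b = two_clouds
        sol = d.kmeans_states(x, 2, seed=1)
        # states are ordered by descending mean |z|: cloud b (around 2) first
        np.testing.assert_allclose(sol.centroids[0], mean_b, atol=0.05)
        np.testing.assert_allclose(sol.centroids[1], mean_a, atol=0.05)
        assert set(sol.labels[:100]) == {2} and set(sol.labels[100:]) == {1}

    def test_all_identical_points_single_state(self):
        x = np.ones((20, 45)) * 0.3
        sol = d.kmeans_states(x, 1, seed=1)
        np.testing.assert_allclose(sol.centroids[0], 0.3)
        assert sol.inertia == pytest.approx(0.0, abs=1e-20)

    def test_multi_restart_dominates_single_restart(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(loc=c, scale=0.4, size=(60, 45)) for c in range(5)])
        multi = d.kmeans_states(x, 5, seed=3, n_init=25)
        single = d.kmeans_states(x, 5, seed=3, n_init=1)
        assert multi.inertia <= single.inertia + 1e-9

    def test_labels_satisfy_nearest_centroid_invariant(self, two_clouds):
        x, _, _ = two_clouds
        sol = d.kmeans_states(x, 2, seed=4)
        expected = d.assign_windows(sol.centroids, x)
        np.testing.assert_array_equal(sol.labels, expected)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            d.kmeans_states(np.zeros((3, 45)), 5, seed=1)

    def test_deterministic_given_seed(self, two_clouds):
        x, _, _ = two_clouds
        a = d.kmeans_states(x, 2, seed=7)
        b = d.kmeans_states(x, 2, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centroids, b.centroids)


class TestAssignWindows:
    def test_centroid_maps_to_own_label(self):
        rng = np.random.default_rng(5)
        cents = rng.normal(size=(4, 45))
        np.testing.assert_array_equal(d.assign_windows(cents, cents), [1, 2, 3, 4])

    def test_equidistant_tie_takes_lower_label(self):
        cents = np.zeros((4, 45))
        cents[1, 0] = 1.0  # state 2 at x=1
        cents[3, 0] = -1.0  # state 4 at x=-1
        cents[0, 1] = 50.0
        cents[2, 1] = 60.0
        point = np.zeros((1, 45))  # equidistant to states 2 and 4
        assert d.assign_windows(cents, point)[0] == 2

    def test_matches_brute_force_search(self):
        rng = np.random.default_rng(6)
        cents = rng.normal(size=(5, 45))
        pts = rng.normal(size=(200, 45))
        got = d.assign_windows(cents, pts)
        brute = [
            1 + min(range(5), key=lambda c: np.sum((p - cents[c]) ** 2)) for p in pts
        ]
        np.testing.assert_array_equal(got, brute)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            d.assign_windows(np.zeros((3, 45)), np.zeros((5, 44)))


class TestMatchStates:
    def _solution(self, cents):
        return d.StateSolution(
            len(cents), np.asarray(cents), np.arange(1, len(cents) + 1), 0.0, 0, 1, 1
        )

    def test_self_match_is_identity_with_unit_r(self):
        rng = np.random.default_rng(7)
        sol = self._solution(rng.normal(size=(5, 45)))
        m = d.match_states(sol, sol)
        assert m.permutation == {i: i for i in range(1, 6)}
        assert all(r == pytest.approx(1.0) for r in m.per_pair_r.values())

    def test_recovers_label_shuffle_and_equals_brute_force(self):
        rng = np.random.default_rng(8)
        cents = rng.normal(size=(5, 45))
        shuffle = [2, 4, 0, 1, 3]
        a = self._solution(cents)
        b = self._solution(cents[shuffle])
        m = d.match_states(a, b)
        # a's state shuffle[j] sits at position j in b
        expected = {shuffle[j] + 1: j + 1 for j in range(5)}
        assert m.permutation == expected
        # Hungarian total equals exhaustive maximum over all 120 bijections
        rmat = np.array(
            [
                [stats.pearsonr(ca, cb).statistic for cb in b.centroids]
                for ca in a.centroids
            ]
        )
        brute = max(
            sum(rmat[i, p[i]] for i in range(5)) for p in itertools.permutations(range(5))
        )
        assert m.total_r == pytest.approx(brute, abs=1e-12)

    def test_noise_perturbation_keeps_permutation(self):
        rng = np.random.default_rng(9)
        cents = rng.normal(size=(5, 45))
        a = self._solution(cents)
        b = self._solution(cents + rng.normal(scale=0.05, size=cents.shape))
        m = d.match_states(a, b)
        assert m.permutation == {i: i for i in range(1, 6)}
        assert min(m.per_pair_r.values()) > 0.9

    def test_unequal_k_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError, match="different k"):
            d.match_states(
                self._solution(rng.normal(size=(4, 45))),
                self._solution(rng.normal(size=(5, 45))),
            )


class TestSelectKMajority:
    def test_single_blob_prefers_smallest_candidate(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(300, 10))
        rep = d.select_k_majority(x, k_range=(2, 3, 4, 5), seed=11, n_init=5)
        assert rep.chosen_k == 2
        assert sum(rep.votes.values()) == len(DEFAULT_INDEX_SET)

    def test_five_separated_blobs_recovered(self):
        rng = np.random.default_rng(12)
        cents = rng.normal(scale=8, size=(5, 10))
        x = np.vstack([c + rng.normal(size=(80, 10)) for c in cents])
        rep = d.select_k_majority(x, seed=12, n_init=5)
        assert rep.chosen_k == 5
        assert rep.votes[5] > len(DEFAULT_INDEX_SET) / 2

    def test_chosen_k_maximizes_votes(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(150, 6))
        rep = d.select_k_majority(x, k_range=(2, 3, 4), seed=13, n_init=3)
        assert rep.votes[rep.chosen_k] == max(rep.votes.values())
        assert set(rep.per_index_choice) == set(DEFAULT_INDEX_SET)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            d.select_k_majority(np.zeros((6, 4)), k_range=(2, 8), seed=1)

    def test_unknown_index_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError, match="unknown"):
            d.select_k_majority(
                rng.normal(size=(50, 4)), index_set=("silhouette", "nope"), seed=1
            )


def test_state_ordering_by_mean_absolute_z():
    rng = np.random.default_rng(15)
    weak = rng.normal(scale=0.05, size=(80, 45))
    strong = rng.normal(loc=1.0, scale=0.05, size=(80, 45))
    sol = d.kmeans_states(np.vstack([weak, strong]), 2, seed=16)
    strengths = np.abs(sol.centroids).mean(axis=1)
    assert strengths[0] > strengths[1]
    assert set(sol.labels[80:]) == {1}
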