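"""JSD metric, PAM clustering, CH index, silhouette and k selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

import kogatype as kt
from kogatype.abundance import ValidationError
from kogatype.cluster import JSD_MAX

from conftest import make_relative


def kl(p, q):
    return sum(pi * math.log(pi / qi) for pi, qi in zip(p, q) if pi > 0)


def jsd_brute(p, q):
    """Term-by-term Jensen-Shannon divergence, natural log."""
    m = [(pi + qi) / 2 for pi, qi in zip(p, q)]
    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def euclid_dm(points):
    d = squareform(pdist(np.asarray(points, dtype=float)))
    return DistanceMatrix(d, ids=[str(i) for i in range(len(points))])


class TestJSD:
    def test_identical_profiles_distance_zero(self):
        t = make_relative([[0.3, 0.7], [0.3, 0.7]])
        d = kt.jsd_distance_matrix(t)
        assert d[("s0", "s1")] == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_supports_hit_metric_bound(self):
        t = make_relative([[1.0, 0.0], [0.0, 1.0]])
        d = kt.jsd_distance_matrix(t)
        assert d[("s0", "s1")] == pytest.approx(JSD_MAX, abs=1e-4)

    def test_matches_bruteforce_summation(self):
        p, q = [0.5, 0.5], [0.25, 0.75]
        t = make_relative([p, q])
        d = kt.jsd_distance_matrix(t, pseudocount=0.0)
        assert d[("s0", "s1")] ** 2 == pytest.approx(jsd_brute(p, q), abs=1e-10)

    def test_valid_distance_matrix_and_order_invariance(self, small_cohort):
        oral, _, _, _ = small_cohort
        rel, _ = kt.prevalence_filter(kt.to_relative(oral))
        d = kt.jsd_distance_matrix(rel)
        arr = np.asarray(d.data)
        assert np.allclose(arr, arr.T, atol=1e-12)
        assert np.diag(arr).max() == 0.0
        assert arr.max() <= JSD_MAX + 1e-9
        perm = np.random.default_rng(0).permutation(rel.n_samples)
        shuffled = kt.AbundanceTable(rel.data.iloc[perm], "relative")
        d2 = kt.jsd_distance_matrix(shuffled)
        for i, j in [(0, 5), (3, 11)]:
            a, b = shuffled.sample_ids[i], shuffled.sample_ids[j]
            assert d2[(a, b)] == pytest.approx(d[(a, b)], abs=1e-12)

    def test_empty_table_rejected(self):
        df = pd.DataFrame(index=[], columns=["a"], dtype=float)
        with pytest.raises(ValidationError, match="empty"):
            kt.jsd_distance_matrix(kt.AbundanceTable(df, "relative"))


class TestPAM:
    def test_two_far_pairs_recovered(self):
        d = euclid_dm([[0, 0], [0, 1], [10, 0], [10, 1]])
        sol = kt.pam(d, 2)
        assert sol.labels[0] == sol.labels[1]
        assert sol.labels[2] == sol.labels[3]
        assert sol.labels[0] != sol.labels[2]

    def test_collinear_k1_medoid_is_middle(self):
        d = DistanceMatrix([[0, 1, 2], [1, 0, 1], [2, 1, 0]], ids=["a", "b", "c"])
        sol = kt.pam(d, 1)
        assert sol.medoid_ids == ("b",)
        assert sol.objective == pytest.approx(2.0)

    def test_k_equal_n_minus_one(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5, 2))
        dist = squareform(pdist(pts))
        d = DistanceMatrix(dist, ids=[str(i) for i in range(5)])
        sol = kt.pam(d, 4)
        sizes = np.bincount(sol.labels)
        assert sorted(sizes) == [1, 1, 1, 2]
        # objective equals the smallest achievable single-pair distance
        best = min(
            dist[:, med].min(axis=1).sum()
            for med in itertools.combinations(range(5), 4)
        )
        assert sol.objective == pytest.approx(best)

    def test_deterministic_and_one_swap_stable(self):
        rng = np.random.default_rng(8)
        d = euclid_dm(rng.normal(size=(30, 3)))
        sol = kt.pam(d, 4)
        sol2 = kt.pam(d, 4)
        np.testing.assert_array_equal(sol.labels, sol2.labels)
        # termination condition: no single medoid/non-medoid exchange improves
        dist = np.asarray(d.data)
        meds = list(sol.medoid_indices)
        for mi in range(4):
            for h in range(30):
                if h in meds:
                    continue
                cand = meds[:mi] + [h] + meds[mi + 1:]
                assert dist[:, cand].min(axis=1).sum() >= sol.objective - 1e-9

    def test_k_out_of_range(self):
        d = euclid_dm([[0, 0], [1, 1]])
        with pytest.raises(ValidationError):
            kt.pam(d, 2)
        with pytest.raises(ValidationError):
            kt.pam(d, 0)

    def test_medoid_carries_own_label(self):
        d = euclid_dm(np.random.default_rng(1).normal(size=(12, 2)))
        sol = kt.pam(d, 3)
        for c, m in enumerate(sol.medoid_indices):
            assert sol.labels[m] == c


class TestCHIndex:
    def test_prefers_true_k_on_separated_clusters(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        d = euclid_dm(pts)
        ch2 = kt.ch_index(d, kt.pam(d, 2))
        ch3 = kt.ch_index(d, kt.pam(d, 3))
        assert ch2 > ch3 > 0

    def test_zero_within_dispersion_is_infinite(self):
        d = DistanceMatrix(
            [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 0], [5, 5, 0, 0]],
            ids=list("abcd"),
        )
        sol = kt.pam(d, 2)
        assert kt.ch_index(d, sol) == math.inf

    def test_empty_cluster_rejected(self):
        d = euclid_dm([[0, 0], [0, 1], [5, 0]])
        sol = kt.pam(d, 2)
        broken = kt.ClusterSolution(
            k=2,
            labels=np.zeros(3, dtype=int),
            medoid_indices=sol.medoid_indices,
            medoid_ids=sol.medoid_ids,
            sample_ids=sol.sample_ids,
            objective=0.0,
        )
        with pytest.raises(ValidationError, match="empty"):
            kt.ch_index(d, broken)


class TestSilhouette:
    def test_tight_far_pairs_score_high(self):
        d = euclid_dm([[0, 0], [0, 0.1], [10, 0], [10, 0.1]])
        assert kt.silhouette_mean(d, kt.pam(d, 2)) > 0.9

    def test_random_labels_score_near_zero(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(200, 4))
        d = euclid_dm(pts)
        labels = rng.integers(0, 2, size=200)
        labels[:2] = [0, 1]
        sol = kt.ClusterSolution(
            k=2,
            labels=labels,
            medoid_indices=np.array([0, 1]),
            medoid_ids=("0", "1"),
            sample_ids=tuple(str(i) for i in range(200)),
            objective=0.0,
        )
        assert abs(kt.silhouette_mean(d, sol)) < 0.1

    def test_singleton_scores_zero(self):
        from sklearn.metrics import silhouette_samples

        d = euclid_dm([[0, 0], [0, 1], [9, 0]])
        labels = np.array([0, 0, 1])
        vals = silhouette_samples(np.asarray(d.data), labels, metric="precomputed")
        assert vals[2] == 0.0


class TestSelectK:
    def test_single_candidate_when_kmax_2(self):
        d = euclid_dm(np.random.default_rng(2).normal(size=(10, 2)))
        report = kt.select_k(d, k_max=2)
        assert report.candidate_ks == (2,)
        assert report.chosen_k == 2

    def test_two_planted_clusters(self, small_cohort):
        oral, _, _, _ = small_cohort
        rel, _ = kt.prevalence_filter(kt.to_relative(oral))
        report = kt.select_k(kt.jsd_distance_matrix(rel), k_max=8)
        assert report.chosen_k == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_three_planted_clusters(self, seed):
        rng = np.random.default_rng(seed)
        blocks = []
        for c in range(3):
            alpha = np.full(30, 0.2)
            alpha[c] *= 80
            comp = rng.dirichlet(alpha, size=15)
            blocks.append(np.array([rng.multinomial(5000, p) for p in comp]))
        df = pd.DataFrame(
            np.vstack(blocks),
            index=[f"s{i}" for i in range(45)],
            columns=[f"t{i}" for i in range(30)],
        )
        rel = kt.to_relative(kt.AbundanceTable(df, "counts"))
        report = kt.select_k(kt.jsd_distance_matrix(rel), k_max=8)
        assert report.chosen_k == 3

    def test_kmax_must_be_below_n(self):
        d = euclid_dm([[0, 0], [1, 0], [2, 0]])
        with pytest.raises(ValidationError):
            kt.select_k(d, k_max=3)
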