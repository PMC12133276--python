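import numpy as np
import pytest
from sklearn.cluster import DBSCAN as SkDBSCAN
from sklearn.metrics import adjusted_rand_score

from asclust.clustering import (
    ClusteringParams,
    auto_params,
    dbscan,
    order_clusters,
    recluster,
)
from asclust.scoring import ScoreMatrix

from conftest import random_score_matrix
from oracles import brute_force_dbscan


def matrix_from(values, ids=None):
    v = np.asarray(values, dtype=float)
    ids = ids or tuple(f"m{i}" for i in range(len(v)))
    return ScoreMatrix(tuple(ids), v)


def two_blob_matrix(n1, n2, within=0.05, between=0.9):
    n = n1 + n2
    v = np.full((n, n), between)
    v[:n1, :n1] = within
    v[n1:, n1:] = within
    np.fill_diagonal(v, 0.0)
    return matrix_from(v)


class TestDbscan:
    def test_all_zero_distances_single_cluster(self):
        score = matrix_from(np.zeros((6, 6)))
        res = dbscan(score, ClusteringParams(eps=0.2, min_samples=5))
        assert res.cluster_sizes == {1: 6}
        assert 0 not in res.labels

    def test_isolated_point_is_noise(self):
        v = np.zeros((5, 5))
        v[-1, :] = v[:, -1] = 1.0
        v[-1, -1] = 0.0
        res = dbscan(matrix_from(v), ClusteringParams(eps=0.2, min_samples=3))
        assert res.labels[-1] == 0
        assert res.cluster_sizes == {1: 4}

    def test_min_samples_larger_than_n_errors(self):
        score = matrix_from(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="exceeds"):
            dbscan(score, ClusteringParams(eps=0.5, min_samples=4))

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 51))
        score = random_score_matrix(rng, n)
        eps = float(rng.uniform(0.05, 1.0))
        min_samples = int(rng.integers(1, n + 1))
        res = dbscan(score, ClusteringParams(eps=eps, min_samples=min_samples))
        raw = brute_force_dbscan(score.values, eps, min_samples)
        expected = order_clusters(raw)
        assert list(res.labels) == list(expected)

    @pytest.mark.parametrize("trial", range(20))
    def test_core_point_partition_agrees_with_sklearn(self, trial):
        """Independent cross-check: same core points, same core co-membership."""
        rng = np.random.default_rng(2000 + trial)
        n = int(rng.integers(8, 40))
        score = random_score_matrix(rng, n)
        eps = float(rng.uniform(0.1, 0.9))
        min_samples = int(rng.integers(2, 8))
        res = dbscan(score, ClusteringParams(eps=eps, min_samples=min_samples))
        sk = SkDBSCAN(eps=eps, min_samples=min_samples,
                      metric="precomputed").fit(score.values)
        core = np.zeros(n, dtype=bool)
        core[sk.core_sample_indices_] = True
        ours = np.array(res.labels)
        assert set(np.nonzero(core)[0]) == {
            i for i in range(n)
            if (score.values[i] <= eps).sum() >= min_samples
        }
        # partitions restricted to core points must be identical
        if core.any():
            assert adjusted_rand_score(ours[core], sk.labels_[core]) == 1.0


class TestOrderClusters:
    def test_larger_cluster_gets_smaller_number(self):
        raw = np.array([5, 5, 5, 9, 9, 9, 9, 9, 9, 9, -1])
        out = order_clusters(raw)
        assert list(out) == [2, 2, 2, 1, 1, 1, 1, 1, 1, 1, 0]

    def test_equal_sizes_tie_broken_by_earliest_member(self):
        raw = np.array([7, 7, 3, 3])
        out = order_clusters(raw)
        assert list(out) == [1, 1, 2, 2]

    def test_all_noise_gives_no_clusters(self):
        out = order_clusters(np.array([-1, -1, -1]))
        assert list(out) == [0, 0, 0]


class TestAutoParams:
    def test_two_blob_eps_between_scales(self):
        score = two_blob_matrix(50, 50)
        params = auto_params(score)
        assert 0.05 <= params.eps < 0.9
        assert params.auto
        res = dbscan(score, params)
        assert res.n_clusters == 2 and 0 not in res.labels

    def test_constant_matrix_falls_back_to_constant(self):
        v = np.full((10, 10), 0.4)
        np.fill_diagonal(v, 0.0)
        params = auto_params(matrix_from(v))
        assert params.eps == pytest.approx(0.4)
        res = dbscan(matrix_from(v), params)
        assert res.n_clusters == 1

    def test_too_few_members_errors(self):
        score = matrix_from(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="at least 5"):
            auto_params(score)

    def test_min_samples_grows_logarithmically(self):
        assert auto_params(two_blob_matrix(50, 50)).min_samples == 5
        big = two_blob_matrix(300, 300)
        assert auto_params(big).min_samples == round(np.log(600))


class TestRecluster:
    def test_pure_cluster_stays_single(self):
        score = matrix_from(np.zeros((6, 6)))
        res = dbscan(score, ClusteringParams(eps=0.2, min_samples=3))
        sub = recluster(res, score, 1, ClusteringParams(eps=0.2, min_samples=3))
        assert sub.cluster_sizes == {1: 6}
        assert sub.member_ids == res.member_ids

    def test_nested_blobs_split_in_two(self):
        # one coarse cluster hiding two tight blobs
        n1 = n2 = 10
        v = np.full((20, 20), 0.3)
        v[:n1, :n1] = 0.02
        v[n1:, n1:] = 0.02
        np.fill_diagonal(v, 0.0)
        score = matrix_from(v)
        res = dbscan(score, ClusteringParams(eps=0.5, min_samples=5))
        assert res.n_clusters == 1
        sub = recluster(res, score, 1, ClusteringParams(eps=0.1, min_samples=5))
        assert sub.n_clusters == 2
        raw = brute_force_dbscan(score.values, 0.1, 5)
        assert list(sub.labels) == list(order_clusters(raw))

    def test_unknown_label_errors(self):
        score = matrix_from(np.zeros((6, 6)))
        res = dbscan(score, ClusteringParams(eps=0.2, min_samples=3))
        with pytest.raises(ValueError, match="99"):
            recluster(res, score, 99)

    def test_subset_smaller_than_min_samples_returns_single_cluster(self):
        score = matrix_from(np.zeros((3, 3)))
        res = dbscan(score, ClusteringParams(eps=0.2, min_samples=2))
        sub = recluster(res, score, 1,
                        ClusteringParams(eps=0.2, min_samples=5))
        assert sub.cluster_sizes == {1: 3}

    def test_full_set_recluster_reproduces_dbscan(self, rng):
        score = random_score_matrix(rng, 30)
        params = ClusteringParams(eps=0.4, min_samples=4)
        res = dbscan(score, params)
        # wrap everything into one cluster, then recluster it with params
        wrapper = dbscan(score, ClusteringParams(eps=1.0, min_samples=1))
        assert wrapper.cluster_sizes == {1: 30}
        sub = recluster(wrapper, score, 1, params)
        assert list(sub.labels) == list(res.labels)


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_well_separated_groups_recovered(self, seed):
        """Between-group distance >= 3x within-group: ARI >= 0.95 with auto
        parameters."""
        from asclust import FamilySpec, build_score_matrix, generate_family
        from asclust.synthetic import true_site_sequences

        fx = generate_family(
            FamilySpec(seed=seed, n_groups=4, members_per_group=25,
                       site_length=10, full_sequence_length=80,
                       p_noise=0.03, p_gap=0.01))
        score = build_score_matrix(true_site_sequences(fx))
        res = dbscan(score, auto_params(score))
        truth = [fx.true_labels[m] for m in res.member_ids]
        assert adjusted_rand_score(truth, res.labels) >= 0.95
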