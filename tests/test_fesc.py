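"""FeSC: pooling, individual clusterings, consensus, centroids, selection."""

import numpy as np
import pytest

from cmcsel.fesc import (
    ConsensusConfig,
    PooledMatrix,
    co_association,
    consensus_clusters,
    fesc_select,
    pool_by_class,
    run_individual_clusterings,
    select_centroids,
)


class TestPooling:
    def test_two_feature_example(self):
        values = np.array([[0.2, 0.5], [0.2, 0.5], [0.8, 0.5], [0.8, 0.5]])
        labels = np.array([1, 1, 2, 2])
        pooled = pool_by_class(values, labels)
        np.testing.assert_allclose(pooled.points, [[0.2, 0.8], [0.5, 0.5]])

    def test_identical_classes_give_equal_coordinates(self):
        rng = np.random.default_rng(0)
        row = rng.uniform(size=6)
        values = np.tile(row, (4, 1))
        pooled = pool_by_class(values, [1, 1, 2, 2])
        np.testing.assert_allclose(pooled.points[:, 0], pooled.points[:, 1])

    def test_matches_groupby_mean_on_random_trials(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(size=(10, 7))
        labels = rng.integers(1, 3, size=10)
        if len(np.unique(labels)) < 2:
            labels[0] = 3 - labels[0]
        pooled = pool_by_class(values, labels)
        for f in range(7):
            assert pooled.points[f, 0] == pytest.approx(values[labels == 1, f].mean())
            assert pooled.points[f, 1] == pytest.approx(values[labels == 2, f].mean())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pool_by_class(np.ones((3, 2)), [1, 1, 1])


def _pooled(points):
    points = np.asarray(points, dtype=float)
    return PooledMatrix(points=points, feature_columns=np.arange(len(points)))


class TestIndividualClusterings:
    def test_two_blobs_split_exactly(self):
        rng = np.random.default_rng(2)
        a = rng.normal([0, 0], 0.01, size=(10, 2))
        b = rng.normal([1, 1], 0.01, size=(10, 2))
        pooled = _pooled(np.vstack([a, b]))
        labs = run_individual_clusterings(
            pooled,
            {"hierarchical": {"n_clusters": 2}, "spectral": {"n_clusters": 2}},
        )
        for lab in labs.values():
            assert len(set(lab[:10])) == 1 and len(set(lab[10:])) == 1
            assert lab[0] != lab[10]

    def test_dbscan_all_noise_below_any_pairwise_distance(self):
        pooled = _pooled([[0, 0], [1, 0], [0, 1], [1, 1]])
        labs = run_individual_clusterings(
            pooled, {"dbscan": {"eps": 0.01, "min_samples": 2}})
        assert np.all(labs["dbscan"] == -1)

    def test_repeated_point_cloud_is_one_cluster(self):
        pooled = _pooled(np.tile([[0.3, 0.4]], (8, 1)) + 1e-6)
        labs = run_individual_clusterings(
            pooled,
            {"hierarchical": {"n_clusters": 1}, "dbscan": {"eps": 0.1, "min_samples": 2}},
        )
        assert len(set(labs["hierarchical"])) == 1
        assert len(set(labs["dbscan"])) == 1

    def test_excess_cluster_count_rejected(self):
        pooled = _pooled([[0, 0], [1, 1]])
        with pytest.raises(ValueError):
            run_individual_clusterings(pooled, {"hierarchical": {"n_clusters": 5}})


class TestConsensus:
    def test_identical_labelings_reproduce_the_common_clustering(self):
        lab = np.array([0, 0, 1, 1, 2, 2])
        clusters = consensus_clusters([lab, lab, lab], sigma=0.9, nu=2)
        assert [sorted(c) for c in clusters] == [[0, 1], [2, 3], [4, 5]]

    def test_five_point_majority_vs_full_agreement(self):
        # algorithms 1 and 2 join {a, b}; algorithm 3 separates them
        l1 = np.array([0, 0, 1, 2, 3])
        l2 = np.array([5, 5, 6, 7, 8])
        l3 = np.array([0, 1, 2, 3, 4])
        A = co_association([l1, l2, l3])
        assert A[0, 1] == pytest.approx(2 / 3)
        joined = consensus_clusters([l1, l2, l3], sigma=0.6, nu=2)
        assert any(set(c) >= {0, 1} for c in joined)
        separated = consensus_clusters([l1, l2, l3], sigma=0.9, nu=2)
        assert not any(set(c) >= {0, 1} for c in separated)

    def test_size_filter_can_empty_the_consensus(self):
        lab = np.array([0, 0, 1, 1, 2])
        assert consensus_clusters([lab, lab], sigma=0.6, nu=3) == []

    def test_co_association_values_and_symmetry(self):
        rng = np.random.default_rng(3)
        labs = [rng.integers(0, 4, size=12) for _ in range(3)]
        A = co_association(labs)
        np.testing.assert_allclose(A, A.T)
        np.testing.assert_allclose(np.diag(A), 1.0)
        assert set(np.round(np.unique(A), 6)) <= {0.0, round(1 / 3, 6),
                                                  round(2 / 3, 6), 1.0}

    def test_high_sigma_components_nested_in_low_sigma_components(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            labs = [rng.integers(0, 5, size=15) for _ in range(3)]
            tight = consensus_clusters(labs, sigma=0.9, nu=1)
            loose = consensus_clusters(labs, sigma=0.6, nu=1)
            for c_tight in tight:
                assert any(set(c_tight) <= set(c_loose) for c_loose in loose)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            consensus_clusters([np.array([0, 0])], sigma=0.0, nu=1)


class TestCentroids:
    def test_member_closest_to_cluster_mean_wins(self):
        pooled = _pooled([[0, 0], [1, 1], [0.4, 0.6]])
        sel = select_centroids([np.array([0, 1, 2])], pooled)
        assert list(sel) == [2]

    def test_singleton_cluster_selects_its_member(self):
        pooled = _pooled([[0.5, 0.5], [0, 0]])
        assert list(select_centroids([np.array([1])], pooled)) == [1]

    def test_symmetric_pair_breaks_tie_to_lower_index(self):
        pooled = _pooled([[0.0, 0.0], [1.0, 1.0]])
        assert list(select_centroids([np.array([0, 1])], pooled)) == [0]

    def test_one_selection_per_cluster_all_unique(self):
        rng = np.random.default_rng(5)
        pooled = _pooled(rng.uniform(size=(20, 2)))
        clusters = [np.arange(0, 7), np.arange(7, 13), np.arange(13, 20)]
        sel = select_centroids(clusters, pooled)
        assert len(sel) == 3 and len(set(sel)) == 3


class TestFescSelect:
    def test_planted_columns_drive_low_holdout_error(self, planted_matrix):
        fm, planted = planted_matrix
        n = fm.n_trials
        rng = np.random.default_rng(6)
        test = rng.choice(n, size=n // 5, replace=False)
        train = np.setdiff1d(np.arange(n), test)
        config = ConsensusConfig(algorithms=("hierarchical", "dbscan"),
                                 svm_c_grid=(1.0, 10.0))
        run = fesc_select(fm.values[train], fm.labels[train], config, seed=0)
        pred = run.model.predict(fm.values[test][:, run.selected_columns])
        assert np.mean(pred != fm.labels[test]) <= 0.1

    def test_shuffled_labels_give_chance_level_cv(self, planted_matrix):
        fm, _ = planted_matrix
        rng = np.random.default_rng(7)
        labels = rng.permutation(fm.labels)
        config = ConsensusConfig(algorithms=("hierarchical", "dbscan"),
                                 svm_c_grid=(1.0,), nu_grid=(2, 5))
        run = fesc_select(fm.values, labels, config, seed=0)
        assert run.cv_mce == pytest.approx(0.5, abs=0.1)

    def test_duplicated_columns_do_not_change_selection_count(self, planted_matrix):
        fm, _ = planted_matrix
        pooled = pool_by_class(fm.values, fm.labels)
        pooled_dup = pool_by_class(np.hstack([fm.values, fm.values]), fm.labels)
        params = {"hierarchical": {"n_clusters": 12},
                  "dbscan": {"eps": 0.04, "min_samples": 2}}
        sel = select_centroids(
            consensus_clusters(list(run_individual_clusterings(pooled, params).values()),
                               0.6, 2), pooled)
        sel_dup = select_centroids(
            consensus_clusters(list(run_individual_clusterings(pooled_dup, params).values()),
                               0.6, 2), pooled_dup)
        assert len(sel_dup) == len(sel)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ConsensusConfig(algorithms=("hierarchical",))
        with pytest.raises(ValueError):
            ConsensusConfig(sigma=1.5)
        with pytest.raises(ValueError):
            ConsensusConfig(nu_grid=(0,))
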