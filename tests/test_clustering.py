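"""k-means fitting, consensus matrices, PAC, k selection and canonical
labelling."""

import warnings

import numpy as np
import pytest

import dcisprofiler as dp
from dcisprofiler.clustering import (assign_clusters, canonicalize_labels,
                                     compute_pac, consensus_cluster,
                                     kmeans_fit, select_k)
from dcisprofiler.errors import ConfigurationError, DataError


def two_clouds(n=200, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.r_[rng.normal(0, 1, (n, 2)), rng.normal(sep, 1, (n, 2))]
    labels = np.r_[np.zeros(n, int), np.ones(n, int)]
    return X, labels


class TestKmeansFit:
    def test_recovers_separated_clouds(self):
        X, truth = two_clouds()
        model = kmeans_fit(X, 2, seed=1)
        labels = assign_clusters(model, X)
        # same partition up to label swap
        a = labels[truth == 0]
        b = labels[truth == 1]
        assert len(set(a)) == 1 and len(set(b)) == 1 and a[0] != b[0]
        sem = 1.0 / np.sqrt(200)
        for centroid in model.centroids:
            target = np.zeros(2) if np.linalg.norm(centroid) < 5 \
                else np.full(2, 10.0)
            assert np.all(np.abs(centroid - target) < 3 * sem)

    def test_deterministic_given_seed(self):
        X, _ = two_clouds(seed=2)
        m1 = kmeans_fit(X, 2, seed=3)
        m2 = kmeans_fit(X, 2, seed=3)
        assert np.array_equal(assign_clusters(m1, X), assign_clusters(m2, X))

    def test_k_below_two_rejected(self):
        X, _ = two_clouds()
        with pytest.raises(ConfigurationError):
            kmeans_fit(X, 1)

    def test_fewer_rows_than_k_rejected(self):
        with pytest.raises(DataError):
            kmeans_fit(np.zeros((3, 2)), 4)


class TestAssign:
    def test_point_at_centroid_and_tie_to_lowest_label(self):
        centroids = np.array([[0.0, 5.0], [0.0, 1.0], [9.0, 9.0],
                              [7.0, -7.0], [0.0, -1.0], [-6.0, 3.0]])
        model = dp.ClusterModel(k=6, centroids=centroids, markers=["a", "b"],
                                n_fitted=10, seed=0)
        assert assign_clusters(model, centroids[2][None, :])[0] == 3
        # origin is equidistant from centroids 2 and 5 -> lowest label wins
        assert assign_clusters(model, np.array([[0.0, 0.0]]))[0] == 2

    def test_fit_assign_consistency(self):
        X, _ = two_clouds(seed=4)
        model = kmeans_fit(X, 2, seed=5)
        labels = assign_clusters(model, X)
        assert np.array_equal(labels, assign_clusters(model, X))


class TestPac:
    def test_crisp_matrix_has_zero_pac(self):
        c = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        assert compute_pac(c) == 0.0

    def test_fully_ambiguous_matrix_has_unit_pac(self):
        c = np.full((4, 4), 0.5)
        np.fill_diagonal(c, 1.0)
        assert compute_pac(c) == 1.0

    def test_mixed_entries_counted_by_hand(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.0
        c[0, 2] = c[2, 0] = 0.5
        c[1, 2] = c[2, 1] = 1.0
        assert compute_pac(c) == pytest.approx(1 / 3)

    def test_bound_entries_are_unambiguous(self):
        c = np.eye(2)
        c[0, 1] = c[1, 0] = 0.9
        assert compute_pac(c, 0.1, 0.9) == 0.0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(3, 51)
            c = rng.random((n, n))
            c = (c + c.T) / 2
            c[rng.random((n, n)) < 0.1] = np.nan
            c = np.where(np.isnan(c) | np.isnan(c.T), np.nan, c)
            np.fill_diagonal(c, 1.0)
            count = total = 0
            for i in range(n):
                for j in range(i + 1, n):
                    if np.isnan(c[i, j]):
                        continue
                    total += 1
                    count += 0.1 < c[i, j] < 0.9
            expected = count / total if total else 0.0
            assert compute_pac(c) == pytest.approx(expected)


class TestSelectK:
    def test_argmin_tie_and_singleton(self):
        assert select_k({2: 0.30, 3: 0.05, 4: 0.20}) == 3
        assert select_k({2: 0.10, 3: 0.10}) == 2
        assert select_k({7: 0.9}) == 7


class TestConsensus:
    def test_separated_data_yields_binary_consensus(self):
        X, _ = two_clouds(n=30, sep=50.0, seed=6)
        res = consensus_cluster(X, k_range=[2], reps=20,
                                subsample_fraction=0.7, seed=6)
        c = res.consensus_matrices[2]
        off = c[np.triu_indices(len(X), 1)]
        off = off[~np.isnan(off)]
        assert np.all((off == 0.0) | (off == 1.0))
        assert res.pac[2] == 0.0

    def test_full_subsample_deterministic_partition(self):
        X, _ = two_clouds(n=25, sep=50.0, seed=7)
        res = consensus_cluster(X, k_range=[2], reps=5,
                                subsample_fraction=1.0, seed=7)
        c = res.consensus_matrices[2]
        off = c[np.triu_indices(len(X), 1)]
        assert np.all((off == 0.0) | (off == 1.0))

    def test_matrix_bounds_and_symmetry(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 3))
        res = consensus_cluster(X, k_range=[2, 3], reps=10,
                                subsample_fraction=0.6, seed=8)
        for c in res.consensus_matrices.values():
            finite = c[~np.isnan(c)]
            assert finite.min() >= 0.0 and finite.max() <= 1.0
            assert np.allclose(np.nan_to_num(c), np.nan_to_num(c.T),
                               atol=1e-12)
            assert np.all(np.diag(c) == 1.0)

    def test_within_cluster_consensus_exceeds_between(self, archetype_cells):
        X, truth = archetype_cells
        idx = np.random.default_rng(9).choice(len(X), 300, replace=False)
        res = consensus_cluster(X[idx], k_range=[6], reps=30,
                                subsample_fraction=0.8, seed=9)
        c = res.consensus_matrices[6]
        t = truth[idx]
        same = t[:, None] == t[None, :]
        iu = np.triu_indices(len(idx), 1)
        within = np.nanmean(c[iu][same[iu]])
        between = np.nanmean(c[iu][~same[iu]])
        assert within > between

    def test_pac_selects_true_k_on_archetype_mixture(self, archetype_cells):
        X, _ = archetype_cells
        idx = np.random.default_rng(10).choice(len(X), 3000, replace=False)
        res = consensus_cluster(X[idx], k_range=range(2, 9), reps=20,
                                subsample_fraction=0.8, seed=10)
        assert res.chosen_k == 6

    def test_invalid_parameters_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ConfigurationError):
            consensus_cluster(X, k_range=[2], reps=1)
        with pytest.raises(ConfigurationError):
            consensus_cluster(X, k_range=[2], reps=5, subsample_fraction=1.5)


class TestCanonicalize:
    def test_shuffled_archetype_centroids_recover_labels(self):
        arch = dp.default_archetypes()
        means = np.array([a.mean_z for a in arch])
        perm = [3, 0, 5, 1, 4, 2]
        model = dp.ClusterModel(k=6, centroids=means[perm],
                                markers=["ER", "HER2", "cMET", "SLC7A5"],
                                n_fitted=100, seed=0)
        canon, mapping = canonicalize_labels(model, arch)
        assert [mapping[i + 1] for i in range(6)] == [p + 1 for p in perm]
        assert np.allclose(canon.centroids, means)

    def test_small_perturbation_keeps_mapping(self):
        arch = dp.default_archetypes()
        means = np.array([a.mean_z for a in arch])
        rng = np.random.default_rng(12)
        model = dp.ClusterModel(k=6,
                                centroids=means + 0.05 * rng.standard_normal(means.shape),
                                markers=["ER", "HER2", "cMET", "SLC7A5"],
                                n_fitted=100, seed=0)
        _, mapping = canonicalize_labels(model, arch)
        assert mapping == {i: i for i in range(1, 7)}

    def test_marker_order_respected(self):
        # model fitted with cMET/HER2 swapped relative to archetype order
        arch = dp.default_archetypes()
        means = np.array([a.mean_z for a in arch])
        reordered = means[:, [0, 2, 1, 3]]  # ER, cMET, HER2, SLC7A5
        model = dp.ClusterModel(k=6, centroids=reordered,
                                markers=["ER", "cMET", "HER2", "SLC7A5"],
                                n_fitted=100, seed=0)
        _, mapping = canonicalize_labels(model, arch)
        assert mapping == {i: i for i in range(1, 7)}

    def test_k_mismatch_warns_and_keeps_labels(self):
        model = dp.ClusterModel(k=2, centroids=np.zeros((2, 4)) + [[0] * 4, [1] * 4],
                                markers=["ER", "HER2", "cMET", "SLC7A5"],
                                n_fitted=10, seed=0)
        with pytest.warns(UserWarning, match="archetypes"):
            out, mapping = canonicalize_labels(model, dp.default_archetypes())
        assert mapping == {1: 1, 2: 2}
        assert np.array_equal(out.centroids, model.centroids)
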