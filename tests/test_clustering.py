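"""Clusterability, cluster-number voting, k-means/PAM/CLARA/hierarchical/SOM."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import adjusted_rand_score as ari

from lgclust import (
    FeatureMatrix,
    clara,
    hierarchical,
    hopkins,
    kmeans,
    pam,
    som_cluster,
    vote_k,
)
from lgclust.som import som_train


def _gauss_blobs(rng, n_per, centers, sd=0.3):
    pts = np.vstack([c + sd * rng.standard_normal((n_per, 2)) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return FeatureMatrix.from_array(pts), labels


@pytest.fixture(scope="module")
def three_blobs():
    rng = np.random.default_rng(0)
    return _gauss_blobs(rng, 300, [(0, 0), (10, 0), (0, 10)])


class TestHopkins:
    def test_uniform_near_half(self):
        rng = np.random.default_rng(1)
        rep = hopkins(rng.uniform(size=(2000, 2)), seed=5)
        assert rep.hopkins == pytest.approx(0.5, abs=0.05)
        assert rep.verdict == "uniform"

    def test_blobs_clusterable(self, three_blobs):
        feats, _ = three_blobs
        rep = hopkins(feats, seed=5)
        assert rep.hopkins > 0.8
        assert rep.verdict == "clusterable"

    def test_deterministic_under_seed(self, three_blobs):
        feats, _ = three_blobs
        assert hopkins(feats, seed=3).hopkins == hopkins(feats, seed=3).hopkins

    def test_degenerate_bbox_rejected(self):
        with pytest.raises(ValueError):
            hopkins(np.zeros((100, 2)), sample=10)


class TestVoteK:
    def test_three_blobs_majority_three(self, three_blobs):
        feats, _ = three_blobs
        rep = vote_k(feats, range(2, 7), seed=0)
        assert rep.majority_k == 3
        assert all(v in rep.k_range for v in rep.index_votes.values())

    def test_single_cloud_prefers_small_k(self):
        rng = np.random.default_rng(2)
        feats = FeatureMatrix.from_array(rng.standard_normal((600, 2)))
        rep = vote_k(feats, range(2, 7), seed=0)
        assert rep.index_votes["gap"] <= 3

    def test_krange_validation(self, three_blobs):
        feats, _ = three_blobs
        with pytest.raises(ValueError):
            vote_k(feats, [1, 2])


class TestPartitional:
    def test_two_blobs_exact_recovery(self):
        rng = np.random.default_rng(3)
        feats, labels = _gauss_blobs(rng, 200, [(0, 0), (10, 10)])
        assert ari(kmeans(feats, 2, seed=0).labels, labels) == 1.0
        assert ari(pam(feats, 2).labels, labels) == 1.0

    def test_pam_k1_medoid_is_exhaustive_minimiser(self):
        rng = np.random.default_rng(4)
        feats = FeatureMatrix.from_array(rng.uniform(size=(300, 3)))
        a = pam(feats, 1)
        D = squareform(pdist(feats.values))
        assert a.medoid_indices[0] == np.argmin(D.sum(axis=1))

    def test_pam_k2_matches_exhaustive_search(self):
        rng = np.random.default_rng(5)
        feats = FeatureMatrix.from_array(rng.uniform(size=(60, 2)))
        D = squareform(pdist(feats.values))
        best, best_cost = None, np.inf
        for i, j in itertools.combinations(range(60), 2):
            cost = np.minimum(D[i], D[j]).sum()
            if cost < best_cost:
                best, best_cost = {i, j}, cost
        a = pam(feats, 2)
        cost_pam = cdist(feats.values, a.centers).min(axis=1).sum()
        assert cost_pam == pytest.approx(best_cost, rel=1e-12)
        assert set(a.medoid_indices) == best

    def test_medoids_are_data_rows(self, three_blobs):
        feats, _ = three_blobs
        a = clara(feats, 3, seed=1)
        for c in a.centers:
            assert np.any(np.all(feats.values == c, axis=1))

    def test_clara_agrees_with_pam(self):
        rng = np.random.default_rng(6)
        feats, labels = _gauss_blobs(rng, 700, [(0, 0), (8, 0), (0, 8)])
        a_pam = pam(feats, 3)
        a_clara = clara(feats, 3, seed=0)
        assert ari(a_pam.labels, a_clara.labels) > 0.95

    def test_clara_sample_size_clamped(self):
        rng = np.random.default_rng(7)
        feats = FeatureMatrix.from_array(rng.uniform(size=(30, 2)))
        with pytest.warns(UserWarning, match="clamped"):
            clara(feats, 2, sample_size=100, seed=0)

    def test_deterministic_under_seed(self, three_blobs):
        feats, _ = three_blobs
        for fn in (lambda: kmeans(feats, 3, seed=9), lambda: clara(feats, 3, seed=9)):
            np.testing.assert_array_equal(fn().labels, fn().labels)

    def test_k_bounds(self, three_blobs):
        feats, _ = three_blobs
        with pytest.raises(ValueError):
            kmeans(feats, feats.n)
        with pytest.raises(ValueError):
            pam(feats, 0)


class TestHierarchical:
    def test_two_pairs_merge_first(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0]])
        res = hierarchical(X)
        merged = {frozenset(res.Z[0, :2].astype(int)), frozenset(res.Z[1, :2].astype(int))}
        assert merged == {frozenset({0, 1}), frozenset({2, 3})}

    def test_cut_recovers_two_blobs(self):
        rng = np.random.default_rng(8)
        feats, labels = _gauss_blobs(rng, 150, [(0, 0), (10, 10)])
        assert ari(hierarchical(feats).cut(2), labels) == 1.0

    def test_leaf_order_is_permutation(self, three_blobs):
        feats, _ = three_blobs
        res = hierarchical(feats)
        assert sorted(res.leaf_order.tolist()) == list(range(feats.n))

    def test_oversize_input_rejected(self):
        with pytest.raises(ValueError, match="subsample"):
            hierarchical(np.zeros((10001, 2)))

    def test_merge_heights_monotone(self, three_blobs):
        feats, _ = three_blobs
        res = hierarchical(feats, method="average")
        assert np.all(np.diff(res.Z[:, 2]) >= -1e-12)


class TestSOM:
    def test_degenerate_grid_learns_centroid(self):
        rng = np.random.default_rng(9)
        X = FeatureMatrix.from_array(rng.standard_normal((400, 3)) + [2.0, -1.0, 0.5])
        model = som_train(X, rows=1, cols=1, epochs=30, seed=0)
        np.testing.assert_allclose(model.codebook[0], X.values.mean(axis=0), atol=0.15)

    def test_three_blobs_recovered(self, three_blobs):
        feats, labels = three_blobs
        model = som_train(feats, rows=10, cols=10, epochs=20, seed=0)
        a = som_cluster(model, feats, 3, seed=0)
        assert ari(a.labels, labels) > 0.9

    def test_quantization_error_settles(self, three_blobs):
        feats, _ = three_blobs
        model = som_train(feats, rows=8, cols=8, epochs=25, seed=1)
        qe = np.array(model.training_log)
        tail = max(1, len(qe) // 5)
        assert qe[-tail:].mean() <= qe[-2 * tail : -tail].mean() + 1e-9

    def test_deterministic_under_seed(self, three_blobs):
        feats, _ = three_blobs
        a = som_train(feats, rows=5, cols=5, epochs=5, seed=4).codebook
        b = som_train(feats, rows=5, cols=5, epochs=5, seed=4).codebook
        np.testing.assert_array_equal(a, b)

    def test_epoch_validation(self, three_blobs):
        feats, _ = three_blobs
        with pytest.raises(ValueError):
            som_train(feats, epochs=0)


class TestCrossMethodStability:
    def test_all_methods_agree_on_blobs(self, three_blobs):
        """k-means, PAM, CLARA, hierarchical-cut and SOM labels all match."""
        feats, _ = three_blobs
        labs = {
            "kmeans": kmeans(feats, 3, seed=0).labels,
            "pam": pam(feats, 3).labels,
            "clara": clara(feats, 3, seed=0).labels,
            "hier": hierarchical(feats).cut(3),
            "som": som_cluster(som_train(feats, rows=8, cols=8, epochs=15, seed=0), feats, 3).labels,
        }
        for a, b in itertools.combinations(labs, 2):
            assert ari(labs[a], labs[b]) > 0.9, (a, b)
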