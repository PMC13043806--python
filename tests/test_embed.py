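"""TF-IDF/LSI embedding, depth filtering, batch adjustment, SNN clustering."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import silhouette_score

from chromtrace.config import ClusterConfig, LSIConfig
from chromtrace.embed import (Embedding, batch_adjust, iterative_lsi,
                              snn_cluster_array, svd_embed, tfidf_transform)
from chromtrace.io import FeatureMatrix


def _matrix(counts, flavor="tile"):
    counts = sp.csr_matrix(np.asarray(counts, dtype=float))
    n, m = counts.shape
    return FeatureMatrix(counts, [f"b{i}" for i in range(n)],
                        [f"f{j}" for j in range(m)], flavor,
                        depth=np.asarray(counts.sum(axis=1)).ravel())


class TestTFIDF:
    def test_matches_hand_computed_formula_on_toy(self):
        # independent recomputation of the stated formula in plain python
        counts = np.array([[2, 0, 1], [0, 3, 1]])
        X, idf = tfidf_transform(_matrix(counts))
        import math
        n = 2
        for j, n_j in enumerate([1, 1, 2]):
            assert idf[j] == pytest.approx(math.log(1 + n / (1 + n_j)))
        for i in range(2):
            row_nnz = 2
            for j in range(3):
                b = 1.0 if counts[i, j] > 0 else 0.0
                expected = math.log(1 + 1e4 * (b / row_nnz) * idf[j])
                assert X[i, j] == pytest.approx(expected)

    def test_zeros_stay_zero(self):
        X, _ = tfidf_transform(_matrix([[1, 0], [1, 1]]))
        assert X[0, 1] == 0.0

    def test_ubiquitous_feature_has_minimum_idf(self):
        _, idf = tfidf_transform(_matrix([[1, 1, 0], [1, 0, 1], [1, 1, 1]]))
        assert idf[0] == pytest.approx(np.log(1 + 3 / 4))
        assert idf[0] == idf.min()

    def test_empty_cell_warns(self):
        with pytest.warns(UserWarning, match="no counts"):
            tfidf_transform(_matrix([[0, 0], [1, 1]]))


class TestSVDEmbed:
    def test_rank_limited_input_yields_tiny_tail_singular_values(self):
        rng = np.random.default_rng(0)
        X = sp.csr_matrix(np.outer(rng.random(40), rng.random(30))
                          + np.outer(rng.random(40), rng.random(30)))
        with pytest.warns(UserWarning, match="rank"):
            coords, basis, kept = svd_embed(X, depth=np.ones(40), n_dims=35)
        s = np.linalg.norm(coords, axis=0)
        assert (s[2:] < 1e-8 * s[0]).all()

    def test_depth_aligned_dimension_is_dropped(self):
        rng = np.random.default_rng(1)
        depth = np.linspace(1, 100, 60)
        # first singular direction = exp-depth pattern, second = noise
        X = sp.csr_matrix(np.outer(np.log(depth), np.ones(20)) * 10
                          + rng.normal(size=(60, 20)) * 0.01)
        coords, basis, kept = svd_embed(X, depth=depth, n_dims=5)
        assert not kept[0]

    def test_basis_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(2)
        X = sp.csr_matrix(rng.random((50, 30)))
        _, basis, _ = svd_embed(X, depth=np.ones(50), n_dims=10)
        np.testing.assert_allclose(basis.T @ basis, np.eye(10), atol=1e-8)
        for j in range(basis.shape[1]):
            assert basis[np.abs(basis[:, j]).argmax(), j] > 0

    def test_reconstruction_error_non_increasing_in_dims(self):
        rng = np.random.default_rng(3)
        dense = rng.random((50, 40))
        X = sp.csr_matrix(dense)
        u_full, s_full, vt_full = np.linalg.svd(dense)  # oracle decomposition
        errors = []
        for k in (2, 5, 10, 20):
            _, basis, _ = svd_embed(X, depth=np.ones(50), n_dims=k,
                                    depth_cor_cutoff=1.1)
            recon = (X @ basis) @ basis.T
            errors.append(np.linalg.norm(dense - recon))
            oracle = np.sqrt((s_full[k:] ** 2).sum())
            assert errors[-1] == pytest.approx(oracle, rel=1e-6)
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))


class TestIterativeLSI:
    def test_small_feature_space_reduces_to_single_svd(self):
        rng = np.random.default_rng(4)
        counts = sp.csr_matrix(rng.poisson(1.0, size=(80, 25)).astype(float))
        m = _matrix(counts.toarray())
        lsi = LSIConfig(n_variable_features=1000, n_dims=10)
        model, emb = iterative_lsi(m, lsi, ClusterConfig(k_param=10), seed=0)
        assert len(model.feature_idx) == 25  # selection vacuous
        X, _ = tfidf_transform(m)
        coords, _, kept = svd_embed(X, m.depth, 10, seed=0)
        np.testing.assert_allclose(np.abs(emb.coords),
                                   np.abs(coords[:, kept]), atol=1e-6)

    def test_planted_clusters_separate(self):
        rng = np.random.default_rng(5)
        blocks = []
        for c in range(3):
            base = np.zeros(60)
            base[c * 20:(c + 1) * 20] = 5.0
            blocks.append(rng.poisson(base + 0.1, size=(50, 60)))
        m = _matrix(np.vstack(blocks))
        model, emb = iterative_lsi(m, LSIConfig(n_dims=10),
                                   ClusterConfig(k_param=15), seed=0)
        labels = np.repeat([0, 1, 2], 50)
        assert silhouette_score(emb.coords, labels) > 0.5

    def test_feature_sets_are_subsets_of_universe(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.poisson(1.0, size=(60, 40)))
        model, _ = iterative_lsi(m, LSIConfig(n_variable_features=30,
                                              n_dims=8),
                                 ClusterConfig(k_param=10), seed=0)
        assert len(model.feature_idx) == 30
        assert model.feature_idx.max() < 40


class TestBatchAdjust:
    def _emb(self, coords):
        return Embedding(np.asarray(coords, float),
                         [f"b{i}" for i in range(len(coords))])

    def test_single_batch_identity(self):
        emb = self._emb(np.random.default_rng(0).normal(size=(10, 3)))
        out = batch_adjust(emb, np.zeros(10))
        np.testing.assert_allclose(out.coords, emb.coords)

    def test_constant_offset_batches_align(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(30, 4))
        emb = self._emb(np.vstack([a, a + 7.0]))
        out = batch_adjust(emb, np.repeat([0, 1], 30))
        m0 = out.coords[:30].mean(axis=0)
        m1 = out.coords[30:].mean(axis=0)
        np.testing.assert_allclose(m0, m1, atol=1e-10)

    def test_planted_batch_shift_improves_cluster_recovery(self):
        rng = np.random.default_rng(2)
        centers = np.array([[0.0, 0.0], [4.0, 4.0]])
        labels = np.tile(np.repeat([0, 1], 40), 2)
        batch = np.repeat([0, 1], 80)
        coords = centers[labels] + rng.normal(scale=0.4, size=(160, 2))
        coords[batch == 1] += np.array([12.0, -9.0])
        emb = self._emb(coords)
        from sklearn.cluster import KMeans
        def acc(c):
            km = KMeans(2, n_init=5, random_state=0).fit_predict(c)
            agree = (km == labels).mean()
            return max(agree, 1 - agree)
        assert acc(batch_adjust(emb, batch).coords) > acc(coords)


class TestSNNCluster:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(3)
        coords = np.vstack([rng.normal(0, 0.3, size=(150, 4)),
                            rng.normal(8, 0.3, size=(150, 4))])
        # resolution 1 may subdivide a dense blob, but never mixes blobs;
        # capping the cluster count merges the subdivisions back
        labels = snn_cluster_array(coords, k_param=30, resolution=1.0, seed=0)
        truth = np.repeat([0, 1], 150)
        for c in np.unique(labels):
            assert len(np.unique(truth[labels == c])) == 1  # purity 1.0
        capped = snn_cluster_array(coords, k_param=30, resolution=1.0,
                                   max_clusters=2, seed=0)
        assert len(np.unique(capped)) == 2
        assert len(np.unique(capped[:150])) == 1
        assert len(np.unique(capped[150:])) == 1

    def test_identical_points_form_one_cluster(self):
        coords = np.zeros((50, 3))
        labels = snn_cluster_array(coords, k_param=10, seed=0)
        assert len(np.unique(labels)) == 1

    def test_max_clusters_enforced_by_merging(self):
        rng = np.random.default_rng(4)
        blobs = [rng.normal(5 * i, 0.1, size=(25, 2)) for i in range(8)]
        labels = snn_cluster_array(np.vstack(blobs), k_param=10,
                                   resolution=1.0, max_clusters=3, seed=0)
        assert len(np.unique(labels)) <= 3

    def test_k_param_must_be_smaller_than_n(self):
        with pytest.raises(ValueError, match="k_param"):
            snn_cluster_array(np.zeros((10, 2)), k_param=10, seed=0)
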