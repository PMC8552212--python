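"""Fuzzy graph invariants (vs brute-force and umap-learn oracles) and the
parametric embedding's training/backfit contracts."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.datasets import make_blobs
from sklearn.manifold import trustworthiness
from sklearn.metrics import silhouette_score

from overprint import ParametricUMAP, backfit, build_fuzzy_graph, rgb_map
from overprint.embed import find_ab_params, smooth_knn_bandwidths


def brute_force_graph(X, k):
    """Independent oracle: full pairwise distances, per-point bisection."""
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1)[:, :k]
    dists = np.take_along_axis(D, order, axis=1)
    rho = dists[:, 0]
    target = np.log2(k)
    sigma = np.empty(len(X))
    for i in range(len(X)):
        lo, hi = 0.0, 1e6
        for _ in range(200):
            mid = (lo + hi) / 2
            s = np.exp(-np.maximum(dists[i] - rho[i], 0) / mid).sum()
            if s > target:
                hi = mid
            else:
                lo = mid
        sigma[i] = (lo + hi) / 2
    return order, dists, rho, sigma


@pytest.fixture(scope="module")
def gauss_points():
    rng = np.random.default_rng(3)
    return rng.normal(size=(300, 6))


class TestFuzzyGraph:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 4))
        g = build_fuzzy_graph(X, k_neighbors=3)
        order, dists, rho, sigma = brute_force_graph(X, 3)
        np.testing.assert_array_equal(g.knn_indices, order)
        np.testing.assert_allclose(g.rho, rho, atol=1e-12)
        np.testing.assert_allclose(g.sigma, sigma, atol=1e-4)

    def test_exact_knn_on_larger_sample(self, gauss_points):
        g = build_fuzzy_graph(gauss_points, k_neighbors=10)
        order, dists, _, _ = brute_force_graph(gauss_points, 10)
        np.testing.assert_allclose(
            np.sort(g.knn_dists, axis=1), np.sort(dists, axis=1), atol=1e-12
        )

    def test_nearest_neighbor_weight_is_one(self, gauss_points):
        g = build_fuzzy_graph(gauss_points, k_neighbors=8)
        w = np.exp(-np.maximum(g.knn_dists - g.rho[:, None], 0) / g.sigma[:, None])
        np.testing.assert_allclose(w[:, 0], 1.0)

    def test_bisection_residual_below_tolerance(self, gauss_points):
        g = build_fuzzy_graph(gauss_points, k_neighbors=15)
        adj = np.maximum(g.knn_dists - g.rho[:, None], 0)
        psum = np.exp(-adj / g.sigma[:, None]).sum(axis=1)
        assert np.abs(psum - np.log2(15)).max() < 1e-5

    def test_symmetrized_matrix_is_symmetric_in_unit_interval(self, gauss_points):
        g = build_fuzzy_graph(gauss_points, k_neighbors=8)
        diff = (g.weights - g.weights.T).tocoo()
        assert np.abs(diff.data).max(initial=0.0) == 0.0
        assert g.weights.data.min() > 0.0
        assert g.weights.data.max() <= 1.0 + 1e-12

    def test_agrees_with_umap_learn_reference(self, gauss_points):
        """umap-learn's bandwidth solver and membership strengths, fed the
        same neighbor lists (self column prepended to match its convention),
        reproduce our graph."""
        umap = pytest.importorskip("umap.umap_")
        import scipy.sparse as sp

        k = 10
        g = build_fuzzy_graph(gauss_points, k_neighbors=k)
        n = g.n_points
        aug_dists = np.hstack([np.zeros((n, 1)), g.knn_dists])
        aug_inds = np.hstack([np.arange(n)[:, None], g.knn_indices])
        sigmas, rhos = umap.smooth_knn_dist(aug_dists, float(k))
        np.testing.assert_allclose(rhos, g.rho, atol=1e-10)
        np.testing.assert_allclose(sigmas, g.sigma, atol=1e-4)
        rows, cols, vals, _ = umap.compute_membership_strengths(
            aug_inds, aug_dists.astype(np.float32),
            sigmas.astype(np.float32), rhos.astype(np.float32)
        )
        W = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        ref = W + W.T - W.multiply(W.T)
        diff = (g.weights - ref).tocoo()
        assert np.abs(diff.data).max(initial=0.0) < 1e-4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            build_fuzzy_graph(np.zeros((5, 2)), k_neighbors=10)


def test_ab_params_match_umap_learn():
    umap = pytest.importorskip("umap.umap_")
    for min_dist in (0.0, 0.1, 0.5):
        a, b = find_ab_params(min_dist)
        a_ref, b_ref = umap.find_ab_params(1.0, min_dist)
        assert a == pytest.approx(a_ref, rel=1e-3)
        assert b == pytest.approx(b_ref, rel=1e-3)


def test_smooth_knn_handles_duplicate_points():
    d = np.zeros((4, 3))
    rho, sigma = smooth_knn_bandwidths(d)
    assert np.all(np.isfinite(sigma)) and np.all(sigma > 0)


@pytest.fixture(scope="module")
def blob_model():
    """3 well-separated Gaussian blobs (200 points each) and a fitted model."""
    X, y = make_blobs(n_samples=600, centers=3, n_features=3, cluster_std=1.0,
                      center_box=(-20, 20), random_state=0)
    model = ParametricUMAP(n_components=2, random_state=0).fit(X)
    return X, y, model


class TestTraining:
    def test_seeded_training_is_reproducible(self, blob_model):
        X, _, model = blob_model
        again = ParametricUMAP(n_components=2, random_state=0).fit(X)
        rms = np.sqrt(np.mean((model.embedding_ - again.embedding_) ** 2))
        assert rms < 1e-4

    def test_blobs_stay_separated_in_embedding(self, blob_model):
        X, y, model = blob_model
        assert silhouette_score(model.embedding_.astype(float), y) > 0.5

    def test_embedding_preserves_local_structure(self, blob_model):
        X, _, model = blob_model
        assert trustworthiness(X, model.embedding_, n_neighbors=10) > 0.95

    def test_duplicated_rows_embed_identically(self, blob_model):
        X, _, model = blob_model
        X2 = np.vstack([X[:5], X[:5]])
        out = model.transform(X2)
        # equal to float32 evaluation tolerance (BLAS may batch rows differently)
        np.testing.assert_allclose(out[:5], out[5:], atol=1e-5)

    def test_loss_decreases(self, blob_model):
        _, _, model = blob_model
        assert model.loss_history_[-1] < model.loss_history_[0]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="50"):
            ParametricUMAP().fit(np.zeros((10, 4)))

    def test_bad_output_dim_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            ParametricUMAP(n_components=5).fit(np.random.default_rng(0).normal(size=(60, 4)))


class TestBackfit:
    def test_backfit_of_training_matrix_reproduces_embedding(self, blob_model):
        X, _, model = blob_model
        np.testing.assert_array_equal(backfit(model, X), model.embedding_)

    def test_row_permutation_equivariance(self, blob_model):
        X, _, model = blob_model
        perm = np.random.default_rng(1).permutation(len(X))
        np.testing.assert_array_equal(
            model.transform(X[perm]), model.transform(X)[perm]
        )

    def test_column_mismatch_rejected(self, blob_model):
        _, _, model = blob_model
        with pytest.raises(ValueError, match="columns"):
            model.transform(np.zeros((5, 7)))

    def test_serialization_round_trip_is_exact(self, blob_model, tmp_path):
        X, _, model = blob_model
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = ParametricUMAP.load(path)
        np.testing.assert_array_equal(loaded.transform(X), model.transform(X))
        assert loaded.training_hash_ == model.training_hash_
        assert loaded.get_params() == model.get_params()


class TestDoseAugmentation:
    def test_requires_integer_counts(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="integer count"):
            ParametricUMAP(dose_augment=0.01).fit(rng.normal(size=(60, 5)))

    def test_thinned_rows_map_near_their_source(self):
        """An encoder trained with dose augmentation places a heavily thinned
        spectrum nearer its own source class than a foreign class."""
        rng = np.random.default_rng(2)
        templates = np.zeros((2, 30))
        templates[0, :10] = 0.4
        templates[1, 15:25] = 0.4
        labels = rng.integers(0, 2, 400)
        X = rng.binomial(100, templates[labels])
        model = ParametricUMAP(n_components=2, dose_augment=1e-2,
                               random_state=0).fit(X.astype(float))
        emb = model.embedding_
        cents = np.array([emb[labels == c].mean(0) for c in (0, 1)])
        thin = rng.binomial(X[:50], 0.02).astype(float)
        coords = model.transform(thin)
        d = ((coords[:, None, :] - cents[None]) ** 2).sum(axis=2)
        acc = (d.argmin(axis=1) == labels[:50]).mean()
        assert acc > 0.9


class TestRgbMap:
    def test_constant_coordinates_render_mid_gray(self):
        img = rgb_map(np.ones((12, 3)), (3, 4))
        np.testing.assert_allclose(img, 0.5)

    def test_values_clipped_to_unit_interval(self):
        rng = np.random.default_rng(0)
        img = rgb_map(rng.normal(size=(100, 3)) * 50, (10, 10))
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_identical_coordinates_share_color(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(50, 3))
        coords[7] = coords[3]
        img = rgb_map(coords, (5, 10))
        np.testing.assert_array_equal(img.reshape(-1, 3)[7], img.reshape(-1, 3)[3])

    def test_wrong_dimension_rejected(self):
        with pytest.raises(ValueError):
            rgb_map(np.zeros((12, 2)), (3, 4))
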