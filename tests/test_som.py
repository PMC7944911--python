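"""Batch SOM training, BMU lookup, second-level K-means, component planes."""

import itertools

import numpy as np
import pytest

from gliosom import (
    SOMModel,
    bmu_index,
    bmu_indices,
    cluster_protoclusters,
    component_planes,
    quantization_error,
    train_som,
)
from gliosom.som import load_model, save_model


def _random_features(rng, n=600, d=6):
    return rng.random((d, n))


class TestTrainSom:
    def test_default_grid_yields_400_protoclusters(self, fitted_som):
        assert fitted_som.grid_shape == (20, 20)
        assert fitted_som.weights.shape == (400, 6)

    def test_identical_inputs_collapse_all_weights(self):
        v = np.array([0.2, 0.4, 0.6, 0.8, 1.0, 1.2])
        X = np.tile(v[:, None], (1, 500))
        som = train_som(X, grid_shape=(5, 5), epochs=5)
        assert np.allclose(som.weights, v)

    def test_training_reduces_quantization_error(self, rng):
        X = _random_features(rng, n=800)
        som = train_som(X, grid_shape=(6, 6), epochs=30)
        qe_init = som.training_meta["initial_quantization_error"]
        qe_final = quantization_error(som, X)
        assert qe_final <= qe_init
        assert np.isclose(qe_final, som.training_meta["final_quantization_error"])

    def test_nan_features_rejected(self, rng):
        X = _random_features(rng, n=100)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN|finite"):
            train_som(X, grid_shape=(3, 3), epochs=2)

    def test_too_few_inputs_suggest_smaller_grid(self, rng):
        with pytest.raises(ValueError, match="smaller grid"):
            train_som(_random_features(rng, n=8), grid_shape=(5, 5))

    def test_fixed_inputs_reproduce_bit_identical_model(self, rng):
        X = _random_features(rng, n=400)
        a = train_som(X, grid_shape=(5, 5), epochs=10, seed=3)
        b = train_som(X, grid_shape=(5, 5), epochs=10, seed=3)
        assert np.array_equal(a.weights, b.weights)


class TestBmu:
    def test_exact_weight_match_returns_that_node(self, rng):
        weights = rng.random((12, 6))
        som = SOMModel((3, 4), weights)
        assert bmu_index(som, weights[7]) == 7

    def test_tie_breaks_toward_lower_index(self):
        weights = np.zeros((6, 6))
        weights[2] = weights[4] = 1.0  # identical nodes
        som = SOMModel((2, 3), weights)
        assert bmu_index(som, np.ones(6)) == 2

    def test_matches_exhaustive_distance_scan(self, rng):
        weights = rng.random((30, 6))
        som = SOMModel((5, 6), weights)
        vectors = rng.random((100, 6))
        got = bmu_indices(som, vectors)
        for v, g in zip(vectors, got):
            dists = [np.linalg.norm(v - w) for w in weights]  # brute force
            assert g == int(np.argmin(dists))

    def test_length_mismatch_rejected(self, rng):
        som = SOMModel((2, 2), rng.random((4, 6)))
        with pytest.raises(ValueError):
            bmu_index(som, np.ones(5))


class TestQuantizationError:
    def test_zero_when_weights_cover_inputs(self, rng):
        X = rng.random((6, 9))
        som = SOMModel((3, 3), X.T)
        assert quantization_error(som, X) == 0.0

    def test_single_node_equals_mean_distance(self, rng):
        X = rng.random((6, 50))
        w = rng.random(6)
        som = SOMModel((1, 1), w[None, :])
        expected = np.mean(np.linalg.norm(X.T - w, axis=1))
        assert np.isclose(quantization_error(som, X), expected)

    def test_matches_direct_loop(self, rng):
        X = rng.random((6, 40))
        som = SOMModel((2, 3), rng.random((6, 6)))
        # independent oracle: per-vector python loop
        total = 0.0
        for x in X.T:
            total += min(np.linalg.norm(x - w) for w in som.weights)
        assert np.isclose(quantization_error(som, X), total / 40)

    def test_empty_features_rejected(self, rng):
        som = SOMModel((2, 2), rng.random((4, 6)))
        with pytest.raises(ValueError):
            quantization_error(som, np.empty((6, 0)))


def _exhaustive_two_means(points):
    """Minimal within-cluster sum of squares over all 2-cluster partitions."""
    best = np.inf
    n = len(points)
    for bits in itertools.product([0, 1], repeat=n):
        if len(set(bits)) < 2:
            continue
        wcss = 0.0
        for c in (0, 1):
            members = points[np.array(bits) == c]
            wcss += np.sum((members - members.mean(axis=0)) ** 2)
        best = min(best, wcss)
    return best


class TestClusterProtoclusters:
    def test_separable_clouds_recovered(self, rng):
        cloud_a = rng.normal(0.0, 0.05, (8, 6))
        cloud_b = rng.normal(5.0, 0.05, (8, 6))
        som = SOMModel((4, 4), np.vstack([cloud_a, cloud_b]))
        part = cluster_protoclusters(som, 2, seed=0, allowed_k=None)
        assert len(set(part.labels[:8])) == 1
        assert len(set(part.labels[8:])) == 1
        assert part.labels[0] != part.labels[8]

    def test_small_instance_attains_exhaustive_optimum(self, rng):
        points = rng.random((8, 6))
        som = SOMModel((2, 4), points)
        part = cluster_protoclusters(som, 2, seed=1, allowed_k=None)
        assert np.isclose(part.kmeans_meta["inertia"], _exhaustive_two_means(points))

    def test_default_k_set_enforced(self, fitted_som):
        cluster_protoclusters(fitted_som, 16, seed=0)  # allowed
        with pytest.raises(ValueError, match="allowed set"):
            cluster_protoclusters(fitted_som, 5, seed=0)

    def test_k_larger_than_nodes_rejected(self, rng):
        som = SOMModel((2, 2), rng.random((4, 6)))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_protoclusters(som, 6, allowed_k=None)

    def test_labels_ordered_by_decreasing_cluster_size(self, partition_k8):
        sizes = np.bincount(partition_k8.labels, minlength=9)[1:]
        assert np.all(np.diff(sizes) <= 0)
        assert sizes.sum() == 400

    def test_fixed_seed_reproduces_partition(self, fitted_som):
        a = cluster_protoclusters(fitted_som, 8, seed=4)
        b = cluster_protoclusters(fitted_som, 8, seed=4)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centroids, b.centroids)


class TestComponentPlanes:
    def test_shapes_match_grid_and_channels(self, fitted_som, partition_k8):
        planes, borders = component_planes(fitted_som, partition_k8)
        assert planes.shape == (6, 20, 20)
        assert borders["horizontal"].shape == (19, 20)
        assert borders["vertical"].shape == (20, 19)

    def test_planes_are_weight_components(self, fitted_som):
        planes, _ = component_planes(fitted_som)
        assert np.array_equal(planes[3].ravel(), fitted_som.weights[:, 3])

    def test_uniform_labels_have_empty_borderline(self, rng):
        som = SOMModel((3, 3), rng.random((9, 6)))
        from gliosom.som import ProtoclusterPartition

        part = ProtoclusterPartition(1, np.ones(9, dtype=int), som.weights[:1].copy())
        _, borders = component_planes(som, part)
        assert not borders["horizontal"].any()
        assert not borders["vertical"].any()

    def test_correlated_t2_adc_channels_give_correlated_planes(self, fitted_som):
        # the generator shares a latent noise field between T2 and ADC, and
        # both channels are elevated together in tumor bulk; their component
        # planes should show similar mapping (positive rank correlation)
        from scipy.stats import spearmanr

        planes, _ = component_planes(fitted_som)
        rho = spearmanr(planes[1].ravel(), planes[3].ravel()).statistic
        assert rho > 0.3

    def test_grid_mismatch_rejected(self, fitted_som, rng):
        other = SOMModel((3, 3), rng.random((9, 6)))
        part = cluster_protoclusters(other, 4, allowed_k=None)
        with pytest.raises(ValueError, match="grid"):
            component_planes(fitted_som, part)


def test_model_archive_round_trip(tmp_path, fitted_som, partition_k8):
    path = tmp_path / "model.npz"
    save_model(path, fitted_som, {8: partition_k8}, config_hash="abc")
    som, partitions = load_model(path)
    assert np.array_equal(som.weights, fitted_som.weights)
    assert som.grid_shape == fitted_som.grid_shape
    assert np.array_equal(partitions[8].labels, partition_k8.labels)
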