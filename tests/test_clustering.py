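"""Tests for the SOM + K-means++ two-level clustering."""

import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import dtci
from dtci._common import FA, FEATURES
from dtci.clustering import ClassPartition, SOMGrid


def _grid_from_codebook(codebook, rows, cols):
    return SOMGrid(rows=rows, cols=cols, codebook=np.asarray(codebook, float),
                   seed=0, epochs=0)


class TestTrainSom:
    def test_identical_inputs_fixed_point(self):
        rng = np.random.default_rng(0)
        v = rng.random(6)
        grid = dtci.train_som(np.tile(v, (300, 1)), rows=4, cols=4, epochs=5, seed=1)
        assert np.allclose(grid.codebook, v)

    def test_quantization_error_improves_with_training(self):
        """Long training on 400 distinct vectors ends at or below the
        initial-codebook quantization error."""
        rng = np.random.default_rng(3)
        X = rng.random((400, 6))
        grid = dtci.train_som(X, rows=8, cols=8, epochs=40, seed=2)
        assert grid.quantization_error <= grid.quantization_errors[0]

    def test_tuning_tail_is_monotone(self, brain_pool):
        grid = dtci.train_som(brain_pool.X[:3000], rows=6, cols=6, epochs=10,
                              seed=0, tuning_epochs=6)
        tail = grid.quantization_errors[10:]
        assert (np.diff(tail) <= 1e-12).all()

    def test_bimodal_codebook_on_two_archetypes(self):
        noise = 0.02
        pal = dtci.make_archetype_palette(n_archetypes=3, separation=0.8,
                                          seed=4, noise=noise)
        rng = np.random.default_rng(5)
        means = np.stack([pal[1].mean, pal[2].mean])
        lab = rng.integers(0, 2, 4000)
        X = np.clip(means[lab] + noise * rng.standard_normal((4000, 6)), 0, 1)
        grid = dtci.train_som(X, rows=6, cols=6, epochs=30, seed=6)
        d = np.linalg.norm(
            grid.codebook[:, None, :] - means[None, :, :], axis=2
        ).min(axis=1)
        assert (d <= 3 * noise * np.sqrt(6)).all()

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            dtci.train_som(np.empty((0, 6)), rows=4, cols=4)

    def test_few_inputs_warn(self, caplog):
        rng = np.random.default_rng(1)
        with caplog.at_level("WARNING", logger="dtci"):
            dtci.train_som(rng.random((10, 6)), rows=4, cols=4, epochs=3)
        assert any("redundant" in r.message for r in caplog.records)

    def test_deterministic_given_seed(self, brain_pool):
        a = dtci.train_som(brain_pool.X[:2000], rows=5, cols=5, epochs=8, seed=9)
        b = dtci.train_som(brain_pool.X[:2000], rows=5, cols=5, epochs=8, seed=9)
        assert np.array_equal(a.codebook, b.codebook)


class TestBestMatchingUnit:
    def test_exact_codebook_row_match(self, trained_grid):
        assert dtci.best_matching_unit(trained_grid, trained_grid.codebook[17]) == 17

    def test_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(2)
        codebook = rng.random((12, 6))
        codebook[9] = codebook[3]  # nodes 3 and 9 equidistant from their value
        grid = _grid_from_codebook(codebook, 3, 4)
        assert dtci.best_matching_unit(grid, codebook[3]) == 3

    def test_brute_force_oracle_1000_vectors(self, trained_grid):
        rng = np.random.default_rng(11)
        X = rng.random((1000, 6))
        got = dtci.bmu_assign(trained_grid, X)
        for i in range(1000):
            expected = int(
                np.argmin(((trained_grid.codebook - X[i]) ** 2).sum(axis=1))
            )
            assert got[i] == expected

    def test_non_finite_vector_rejected(self, trained_grid):
        with pytest.raises(ValueError):
            dtci.best_matching_unit(trained_grid, np.array([np.nan] * 6))


class TestClusterProtoclusters:
    def test_k1_wcss_equals_weighted_variance(self, trained_grid, node_weights):
        part = dtci.cluster_protoclusters(
            trained_grid, K=1, seed=0, node_weights=node_weights
        )
        w = node_weights
        mean = (w[:, None] * trained_grid.codebook).sum(0) / w.sum()
        expected = (w[:, None] * (trained_grid.codebook - mean) ** 2).sum()
        assert np.isclose(part.wcss, expected, rtol=1e-6)

    def test_k_saturation_wcss_zero(self):
        rng = np.random.default_rng(7)
        grid = _grid_from_codebook(rng.random((12, 6)), 3, 4)
        part = dtci.cluster_protoclusters(grid, K=12, seed=1)
        assert part.wcss < 1e-20
        assert len(np.unique(part.node_to_class)) == 12

    def test_k_exceeding_distinct_vectors_rejected(self):
        codebook = np.tile(np.linspace(0, 1, 6), (8, 1))
        grid = _grid_from_codebook(codebook, 2, 4)
        with pytest.raises(ValueError):
            dtci.cluster_protoclusters(grid, K=2, seed=0)

    def test_k2_recovers_planted_bimodality(self):
        rng = np.random.default_rng(8)
        lo = 0.1 + 0.02 * rng.random((20, 6))
        hi = 0.9 - 0.02 * rng.random((16, 6))
        grid = _grid_from_codebook(np.vstack([lo, hi]), 6, 6)
        truth = np.array([0] * 20 + [1] * 16)
        part = dtci.cluster_protoclusters(grid, K=2, seed=3)
        assert adjusted_rand_score(truth, part.node_to_class) == 1.0

    def test_all_labels_used(self, trained_grid, node_weights):
        for K in (4, 6, 10):
            part = dtci.cluster_protoclusters(
                trained_grid, K=K, seed=5, node_weights=node_weights
            )
            assert set(part.node_to_class) == set(range(1, K + 1))

    def test_deterministic_given_seed(self, trained_grid, node_weights):
        a = dtci.cluster_protoclusters(trained_grid, 6, seed=4,
                                       node_weights=node_weights)
        b = dtci.cluster_protoclusters(trained_grid, 6, seed=4,
                                       node_weights=node_weights)
        assert np.array_equal(a.node_to_class, b.node_to_class)


class TestOrderClasses:
    def test_diffuse_class_gets_top_label(self):
        """The high-diffusivity / low-anisotropy centroid takes the highest
        class number (the necrosis-like end of the ordering)."""
        centroids = np.array(
            [[0.0, 0.0, 1.0, 1.0, 1.0, 1.0],  # low DWI/FA, high S0/MD/AD/RD
             [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]]
        )
        grid = _grid_from_codebook(np.repeat(centroids, 2, axis=0), 2, 2)
        part = ClassPartition(K=2, node_to_class=np.array([1, 1, 2, 2]),
                              class_centroids=centroids, seed=0, wcss=0.0)
        ordered = dtci.order_classes(part, grid)
        assert ordered.node_to_class.tolist() == [2, 2, 1, 1]

    def test_idempotent(self, trained_grid, partition6):
        again = dtci.order_classes(partition6, trained_grid)
        assert np.array_equal(again.node_to_class, partition6.node_to_class)
        assert np.array_equal(again.class_centroids, partition6.class_centroids)

    @pytest.mark.parametrize("perm_seed", range(10))
    def test_invariant_to_input_labeling(self, trained_grid, partition6, perm_seed):
        rng = np.random.default_rng(perm_seed)
        perm = rng.permutation(partition6.K)  # old label k -> perm[k-1]+1
        relabeled = ClassPartition(
            K=partition6.K,
            node_to_class=perm[partition6.node_to_class - 1] + 1,
            class_centroids=partition6.class_centroids[np.argsort(perm)],
            seed=0, wcss=partition6.wcss,
        )
        ordered = dtci.order_classes(relabeled, trained_grid)
        assert np.array_equal(ordered.node_to_class, partition6.node_to_class)


class TestComponentPlanes:
    def test_planes_equal_codebook_columns(self, trained_grid, partition6):
        planes = dtci.export_component_planes(trained_grid, partition6)
        for j, f in enumerate(FEATURES):
            assert np.array_equal(
                planes.planes[f].ravel(), trained_grid.codebook[:, j]
            )

    def test_max_fa_node_in_top_fa_class(self, trained_grid, partition6):
        planes = dtci.export_component_planes(trained_grid, partition6)
        node = int(np.argmax(trained_grid.codebook[:, FA]))
        top_fa_class = int(np.argmax(partition6.class_centroids[:, FA])) + 1
        assert planes.class_map.ravel()[node] == top_fa_class


class TestTwoLevelAgreement:
    def test_som_km_agrees_with_direct_kmeans(self, brain_pool, trained_grid,
                                              node_weights, partition6):
        """On well-separated archetypes the two-level voxel labels agree
        with direct K-means on the voxels (ARI >= 0.8)."""
        X = brain_pool.X
        two_level = dtci.assign_voxel_classes(trained_grid, partition6, X)
        direct = KMeans(n_clusters=6, n_init=5, random_state=0).fit_predict(X)
        assert adjusted_rand_score(two_level, direct) >= 0.8
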