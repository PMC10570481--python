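"""Shared fixtures: a small synthetic cohort and clustering objects.

Expensive objects (cohort, pooled voxels, trained SOM) are session-scoped;
tests that mutate state build their own copies.
"""

from __future__ import annotations

import numpy as np
import pytest

import dtci


@pytest.fixture(scope="session")
def palette():
    return dtci.make_archetype_palette(n_archetypes=6, separation=0.5, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    subjects, cohort, truth = dtci.simulate_cohort(
        n_per_group=(8, 5), seed=7, roi_size_range=(120, 400)
    )
    return subjects, cohort, truth


@pytest.fixture(scope="session")
def normalized_subjects(small_cohort):
    subjects, _, _ = small_cohort
    return [(dtci.normalize_features(s.maps), s.roi) for s in subjects]


@pytest.fixture(scope="session")
def brain_pool(normalized_subjects):
    return dtci.pool_voxels(normalized_subjects, scope="brain")


@pytest.fixture(scope="session")
def roi_pool(normalized_subjects):
    return dtci.pool_voxels(normalized_subjects, scope="roi")


@pytest.fixture(scope="session")
def trained_grid(brain_pool):
    return dtci.train_som(brain_pool, rows=10, cols=10, epochs=20, seed=1)


@pytest.fixture(scope="session")
def node_weights(trained_grid, brain_pool):
    return dtci.node_voxel_counts(trained_grid, brain_pool.X)


@pytest.fixture(scope="session")
def partition6(trained_grid, node_weights):
    return dtci.cluster_protoclusters(
        trained_grid, K=6, seed=2, node_weights=node_weights
    )


@pytest.fixture(scope="session")
def grade_labels(small_cohort):
    _, cohort, _ = small_cohort
    return (cohort.grade_group == "high").astype(int).to_numpy()


@pytest.fixture(scope="session")
def log_ratio_features(trained_grid, partition6, roi_pool):
    counts_nodes, sids = dtci.node_count_matrix(trained_grid, roi_pool)
    counts = dtci.class_counts_from_nodes(counts_nodes, partition6)
    profs = dtci.profiles_from_counts(counts, sids, partition6.K)
    return np.stack([p.log_ratios for p in profs]), profs
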