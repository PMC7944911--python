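"""Shared fixtures: a small synthetic cohort carried through the pipeline."""

import numpy as np
import pytest

from gliosom import (
    CohortSpec,
    SVMConfig,
    cluster_protoclusters,
    compute_normalization,
    extract_training_voxels,
    generate_cohort,
    stack_cohort_features,
    train_som,
)
from gliosom.features import build_feature_tables


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(
        n_subjects=10,
        class_balance=0.5,
        volume_shape=(32, 32, 32),
        tumor_radius_range=(4, 6),
        seed=123,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_studies(small_cohort):
    return [s.study for s in small_cohort[0]]


@pytest.fixture(scope="session")
def norm_params(small_studies):
    return {s.subject_id: compute_normalization(s) for s in small_studies}


@pytest.fixture(scope="session")
def feature_matrix(small_studies, norm_params):
    blocks = [extract_training_voxels(s, norm_params[s.subject_id]) for s in small_studies]
    return stack_cohort_features(blocks, [s.subject_id for s in small_studies])


@pytest.fixture(scope="session")
def fitted_som(feature_matrix):
    return train_som(feature_matrix, epochs=20, seed=5)


@pytest.fixture(scope="session")
def partition_k8(fitted_som):
    return cluster_protoclusters(fitted_som, 8, seed=5)


@pytest.fixture(scope="session")
def table_k8(small_studies, norm_params, fitted_som, partition_k8):
    return build_feature_tables(small_studies, norm_params, fitted_som, {8: partition_k8})[8]


@pytest.fixture(scope="session")
def svm_config():
    return SVMConfig(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
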