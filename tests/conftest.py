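import numpy as np
import pytest

from bagpipe import FeatureTable, SyntheticConfig, generate_cohort


@pytest.fixture
def tiny_feature_table() -> FeatureTable:
    return FeatureTable(
        modality="T1",
        subject_ids=["s1", "s2", "s3"],
        feature_names=["f1", "f2"],
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A scaled-down study: enough subjects/features for the boosted
    trees to learn the age signal, small enough for fast tests."""
    return SyntheticConfig(
        n_train=150,
        n_patient=60,
        n_features_t1=24,
        n_features_dti=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohorts(small_config):
    train = generate_cohort(small_config, "training")
    patient = generate_cohort(small_config, "patient")
    return train, patient
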