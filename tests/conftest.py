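import numpy as np
import pytest

from eegfusion import (DatasetSpec, ModelConfig, extract_features,
                       generate_dataset, seed_like_classes)
from eegfusion.features4d import seed62_grid


@pytest.fixture(scope="session")
def small_spec() -> DatasetSpec:
    """3 subjects × 3 classes × 2 trials of 12 s — enough for 2 fragments per
    trial and fast enough for unit tests."""
    return DatasetSpec(n_subjects=3, trials_per_class=2,
                       classes=seed_like_classes(), duration_s=12.0,
                       fs=200.0, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return extract_features(small_dataset, grid=seed62_grid())


@pytest.fixture(scope="session")
def tiny_model_config() -> ModelConfig:
    return ModelConfig(n_classes=2, input_shape=(6, 8, 9, 4),
                       cnn_channels=(2, 3), bilstm_hidden=2,
                       dcign_channels=(2, 3), latent_dim=2,
                       fusion_hidden=(4,))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
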