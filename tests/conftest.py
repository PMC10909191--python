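import numpy as np
import pytest

from anxeeg.features import extract_features
from anxeeg.labeling import label_dataset
from anxeeg.pipeline import PipelineConfig, preprocess_dataset
from anxeeg.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale cohort: 4 subjects × 6 trials of 5 s, clear class effect."""
    return SimulationConfig(
        n_subjects=4, trial_seconds=5.0, effect_size=2.0, anxious_fraction=0.5, seed=3
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_epochs(small_config, small_dataset):
    pipe = PipelineConfig(seed=3, simulation=small_config)
    return preprocess_dataset(small_dataset, pipe)


@pytest.fixture(scope="session")
def one_epoch(small_epochs):
    return small_epochs[0]


@pytest.fixture(scope="session")
def labeled_psd_table(small_epochs, small_dataset):
    labels = label_dataset(small_epochs, small_dataset.annotations, "hama")
    return extract_features(small_epochs, method="psd", labels=labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
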