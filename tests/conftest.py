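import numpy as np
import pytest

from dssa.pipeline import preprocess_trials
from dssa.synthetic import ChoiceDatasetSpec, generate_choice_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small labeled choice dataset with known ground truth."""
    spec = ChoiceDatasetSpec(
        n_subjects=30, p=5, d=3, T=256, effect_size=0.4, prevalence=0.7, seed=5
    )
    trials, truth = generate_choice_dataset(spec)
    return trials, truth, spec


@pytest.fixture(scope="session")
def small_processed(small_dataset):
    """The same trials after band-pass filtering and prewhitening."""
    trials, truth, spec = small_dataset
    return preprocess_trials(trials), truth, spec
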