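import numpy as np
import pytest

from mirpanel import ClassifierConfig, SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A modest shift dataset shared by tests that only need plausible data."""
    spec = SyntheticSpec(
        s_tumor=30, s_control=30, d=40, n_planted=4, effect_size=4.0,
        noise_sd=1.0, seed=7,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_xy(small_dataset):
    return small_dataset.log2_rpm(), small_dataset.labels


@pytest.fixture()
def clf_config():
    return ClassifierConfig(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
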