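import numpy as np
import pytest

from wcos.experiments import make_dataset
from wcos.windowing import NORMAL, ABNORMAL, slice_windows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small synthetic cohort shared by the slower pipeline tests:
    12 normal / 6 abnormal records with a strong (0.8) murmur."""
    return make_dataset(n_normal=12, n_abnormal=6, murmur_rel_amplitude=0.8, seed=7)


@pytest.fixture(scope="session")
def tiny_windows(tiny_cohort):
    windows = [s for r in tiny_cohort for s in slice_windows(r)]
    normal = [s for s in windows if s.label == NORMAL]
    abnormal = [s for s in windows if s.label == ABNORMAL]
    return windows, normal, abnormal
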