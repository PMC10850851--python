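import numpy as np
import pytest

from ddst.item_bank import default_item_bank
from ddst.simulate import SimConfig, TrialDesign


@pytest.fixture(scope="session")
def bank():
    return default_item_bank()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sim_config():
    return SimConfig()


@pytest.fixture
def small_design():
    return TrialDesign(n_nurses=4, patients_per_nurse_per_modality=2, n_patients=10)
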