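import numpy as np
import pytest

from t4circuit import synth
from t4circuit.stimuli import EdgeSpec, make_edge


@pytest.fixture(scope="session")
def gt():
    """Default ground-truth circuit (fitted parameters, canonical detector)."""
    return synth.default_ground_truth()


@pytest.fixture(scope="session")
def pd_on_movie():
    """ON edge moving in the preferred direction with a 0.5 s dark pre-roll."""
    return make_edge(EdgeSpec("ON", 0.0, 30.0, pad_s=0.5))


@pytest.fixture(scope="session")
def nd_on_movie():
    return make_edge(EdgeSpec("ON", 180.0, 30.0, pad_s=0.5))


@pytest.fixture(scope="session")
def fit_dataset(gt):
    """Noiseless four-condition dataset shared by inference tests."""
    return synth.synth_fit_dataset(gt, noise_sd_mV=0.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
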