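import warnings

import numpy as np
import pytest

from eegaffect.headmodel import HeadModel
from eegaffect.pipeline import run_pipeline
from eegaffect.stimuli import generate_schedule, generate_stimulus_set
from eegaffect.validation import scaled_pipeline_config


@pytest.fixture(scope="session")
def head64():
    return HeadModel.standard(64)


@pytest.fixture(scope="session")
def head24():
    return HeadModel.standard(24)


@pytest.fixture(scope="session")
def stimuli160():
    return generate_stimulus_set(40, seed=7)


@pytest.fixture(scope="session")
def schedule8(stimuli160):
    return generate_schedule(stimuli160, n_sessions=8, seed=7)


@pytest.fixture(scope="session")
def demo_result():
    """One fully analysed desk-scale cohort, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(scaled_pipeline_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
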