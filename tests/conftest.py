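import logging

import numpy as np
import pytest

from gaitevents import default_config, detect_events, make_trial

logging.getLogger("gaitevents").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def default_trial():
    """Default study conditions: 10 cycles, 1000 Hz, noise sigma 0.2 m/s^2."""
    return make_trial(seed=1)


@pytest.fixture(scope="session")
def noiseless_trial():
    return make_trial(seed=1, noise_sigma=0.0, drift_amp=0.0)


@pytest.fixture(scope="session")
def default_result(default_trial, cfg):
    return detect_events(default_trial.heel_rec, default_trial.toe_rec, cfg)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_trial, cfg):
    return detect_events(noiseless_trial.heel_rec, noiseless_trial.toe_rec, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
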