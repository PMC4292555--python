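import numpy as np
import pytest

from ecogwarp import RunConfig, SessionParams, generate_session, process_session


@pytest.fixture(scope="session")
def default_params():
    """Study-condition generator defaults with a small trial count."""
    return SessionParams(n_trials=12, seed=101)


@pytest.fixture(scope="session")
def session12(default_params):
    """A 12-trial session under the default (jittered) study conditions."""
    return generate_session(default_params)


@pytest.fixture(scope="session")
def processed12(session12):
    return process_session(session12, RunConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
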