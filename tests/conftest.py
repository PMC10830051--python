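import numpy as np
import pytest

from spocrt import SimConfig, fit_participant, preprocess_session, simulate_participant


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size participant: 8 channels, 100 Hz, 64 trials."""
    return SimConfig(n_channels=8, sampling_rate=100.0, n_trials=64,
                     pool_size=128, seed=7)


@pytest.fixture(scope="session")
def small_participant(small_config):
    task, rest = simulate_participant(small_config)
    return task, rest


@pytest.fixture(scope="session")
def fitted_participant(small_participant):
    """One fully fitted small participant (model, train set, hold-out set)."""
    task, rest = small_participant
    epochs = preprocess_session(task, None, ica_mode="none")
    return fit_participant(epochs)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
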