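import numpy as np
import pytest

from strokebci import EpochSet, SimConfig, generate_session, prepare_bundle


@pytest.fixture(scope="session")
def small_config():
    """Two runs of 10+10 trials: 40 trials, quick to simulate."""
    return SimConfig(seed=51, n_runs=2, trials_per_class_per_run=10)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_session):
    return prepare_bundle(small_session)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free oscillators with constant amplitude: analytic ERD ground truth."""
    return SimConfig(seed=77, n_runs=2, trials_per_class_per_run=10,
                     erd_depth_left=0.5, erd_depth_right=0.5,
                     background_rms_uv=0.0, sensor_noise_sd=0.0,
                     amplitude_mod=0.0)


@pytest.fixture(scope="session")
def clean_session(clean_config):
    return generate_session(clean_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_epochs(data, labels, channel_names=None, fs=250.0, window=(0.0, 4.0),
                role="task"):
    """Wrap raw arrays into an EpochSet for pipeline-level tests."""
    data = np.asarray(data, dtype=float)
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(data.shape[1]))
    return EpochSet(data=data, labels=np.asarray(labels, dtype=int),
                    channel_names=tuple(channel_names), sampling_rate_hz=fs,
                    window=window, role=role)
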