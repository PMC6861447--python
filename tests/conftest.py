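import numpy as np
import pytest

import reachkin as rk
from reachkin.config import PipelineConfig


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture()
def block_spec():
    return rk.default_trial_spec("block", seed=42)


@pytest.fixture()
def noiseless_block_spec():
    return rk.default_trial_spec(
        "block", seed=42, accel_noise_sd=0.0, gyro_noise_sd=0.0,
        marker_noise_sd=0.0)


@pytest.fixture()
def block_pair(block_spec):
    """(ImuTrial, MarkerTrial, GroundTruth) for one noisy block trial."""
    return rk.simulate_pair(block_spec)


def make_static_imu_trial(n=600, rate=100.0, noise=0.0, seed=0,
                          task="block"):
    """A trial in which the sensor never moves (pronated, z up)."""
    rng = np.random.default_rng(seed)
    acc = np.zeros((n, 3))
    acc[:, 2] = 1.0
    gyr = np.zeros((n, 3))
    if noise > 0:
        acc += rng.normal(0, noise, acc.shape)
        gyr += rng.normal(0, 0.5, gyr.shape)
    return rk.ImuTrial(t=np.arange(n) / rate, acc=acc, gyr=gyr, rate=rate,
                       task=task, trial_id="static")
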