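import numpy as np
import pytest

from tiltframe.imu import estimate_orientation, kinematic_derivatives
from tiltframe.synthetic import SimulationConfig, simulate_head_kinematics


@pytest.fixture(scope="session")
def short_session():
    """120 s default-noise session with ground truth and estimated orientation."""
    cfg = SimulationConfig(duration=120.0, seed=7)
    kin, truth = simulate_head_kinematics(cfg)
    orient = estimate_orientation(kin)
    return kin, truth, orient


@pytest.fixture(scope="session")
def short_derived(short_session):
    kin, truth, orient = short_session
    return kinematic_derivatives(kin, orient)


@pytest.fixture(scope="session")
def noiseless_session():
    cfg = SimulationConfig(duration=120.0, seed=3, accel_noise_sd=0.0, gyro_noise_sd=0.0)
    kin, truth = simulate_head_kinematics(cfg)
    orient = estimate_orientation(kin)
    return kin, truth, orient


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
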