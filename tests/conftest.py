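import numpy as np
import pytest

from wristkin import ImuStream, NoiseModel
from wristkin.fusion import GRAVITY, euler_to_matrix


@pytest.fixture
def static_stream_factory():
    """Build a noise-free static stream at a fixed attitude."""

    def make(euler_deg=(0.0, 0.0, 0.0), duration=2.0, rate=50.0, sensor_id="S2",
             gyro=(0.0, 0.0, 0.0)):
        n = int(round(duration * rate)) + 1
        t = np.arange(n) / rate
        R = euler_to_matrix(np.asarray(euler_deg, dtype=float))
        accel = np.tile(R.T @ np.array([0.0, 0.0, GRAVITY]), (n, 1))
        g = np.tile(np.asarray(gyro, dtype=float), (n, 1))
        return ImuStream(sensor_id, t, accel, g, rate)

    return make


@pytest.fixture
def quiet_noise():
    return NoiseModel.none()
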