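import numpy as np
import pytest

from rotorswitch import SpeedTrace


@pytest.fixture
def constant_speed():
    """Factory for uniform-rate speed traces."""

    def make(speed_hz: float, duration_s: float = 1.0, frame_rate_hz: float = 1000.0):
        n = int(round(duration_s * frame_rate_hz))
        t = np.arange(n) / frame_rate_hz
        return SpeedTrace(time_s=t, speed_hz=np.full(n, float(speed_hz)),
                          frame_rate_hz=frame_rate_hz)

    return make


@pytest.fixture
def speed_from_values():
    """Wrap an explicit speed sample sequence at 1 frame/s."""

    def make(values, frame_rate_hz: float = 1.0):
        v = np.asarray(values, dtype=float)
        t = np.arange(v.size) / frame_rate_hz
        return SpeedTrace(time_s=t, speed_hz=v, frame_rate_hz=frame_rate_hz)

    return make
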