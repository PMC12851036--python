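import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def quiet_sensor():
    """Noise- and drift-free sensor for deterministic waveform checks."""
    from gazestrain.simulate import SensorSpec

    return SensorSpec(noise_sd=0.0, drift_amplitude=0.0)


@pytest.fixture(scope="session")
def single_event_recordings(quiet_sensor):
    """One clean 12° recording per cardinal direction, keyed by direction."""
    from gazestrain.simulate import GazeEvent, generate_recording

    out = {}
    for d in ("up", "down", "left", "right"):
        ev = GazeEvent(onset=2.0, hold_duration=0.35, direction=d, angle_deg=12.0)
        out[d] = generate_recording([ev], sensor=quiet_sensor, duration=6.0, seed=0)
    return out


def brute_force_dtw(a, b):
    """Independent recursive DTW oracle (exponential; tiny sequences only)."""
    from functools import lru_cache

    a = tuple(a)
    b = tuple(b)

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0 and j == 0:
            return 0.0
        if i == 0 or j == 0:
            return float("inf")
        return abs(a[i - 1] - b[j - 1]) + min(rec(i - 1, j - 1), rec(i - 1, j), rec(i, j - 1))

    return rec(len(a), len(b))


def shoelace(points):
    """Independent polygon-area oracle."""
    total = 0.0
    n = len(points)
    for i in range(n):
        x1, y1 = points[i]
        x2, y2 = points[(i + 1) % n]
        total += x1 * y2 - x2 * y1
    return abs(total) / 2.0
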