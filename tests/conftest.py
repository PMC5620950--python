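import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fallwatch.detection import DetectorConfig
from fallwatch.imu_io import DerivedTrace
from fallwatch.simulator import default_spec, simulate_activity

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_cfg() -> DetectorConfig:
    return DetectorConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_trace(rms, pitch=None, roll=None, yaw=None, rate=100.0, segment="waist"):
    """Build a DerivedTrace from channel arrays (zeros where omitted)."""
    rms = np.asarray(rms, dtype=float)
    n = rms.size
    zeros = np.zeros(n)
    return DerivedTrace(
        t=np.arange(n) / rate,
        rms=rms,
        yaw=zeros if yaw is None else np.asarray(yaw, float),
        pitch=zeros if pitch is None else np.asarray(pitch, float),
        roll=zeros if roll is None else np.asarray(roll, float),
        rate=rate,
        segment=segment,
    )


@pytest.fixture
def flat_trace() -> DerivedTrace:
    """10 s of quiet standing: RMS 1 g, all angles zero."""
    return make_trace(np.ones(1000))


@pytest.fixture
def waist_fall():
    """A seeded forward fall on the waist."""
    return simulate_activity(default_spec("forward_fall_lying", "waist"), seed=7)


def random_trace(rng: np.random.Generator, n: int = 600, rate: float = 100.0):
    """A random trace with occasional spikes and angle excursions.

    Used for batch/streaming equivalence and monotonicity properties: the
    marginal distributions straddle both detector thresholds so all code
    paths (crossings, windows, alarms, truncation) get exercised.
    """
    rms = np.abs(1.0 + rng.normal(0, 0.3, n))
    for _ in range(rng.integers(0, 4)):
        i = int(rng.integers(0, n))
        rms[i : i + int(rng.integers(1, 30))] += rng.uniform(0.5, 4.0)
    pitch = np.clip(rng.normal(0, 25, n), -90, 90)
    roll = np.clip(rng.normal(0, 25, n), -179, 180)
    return make_trace(rms, pitch=pitch, roll=roll)
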