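import numpy as np
import pytest

from kinemagree import JointTrajectorySet, ScalarSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trajectory(points: dict, timestamps, valid=None, rate=None) -> JointTrajectorySet:
    """Build a JointTrajectorySet from {joint: (n,3) array or (3,) constant}."""
    timestamps = np.asarray(timestamps, dtype=float)
    n = len(timestamps)
    names, arrays = [], []
    for name, p in points.items():
        p = np.asarray(p, dtype=float)
        if p.ndim == 1:
            p = np.tile(p, (n, 1))
        names.append(name)
        arrays.append(p)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(timestamps))) if n > 1 else 1.0
    return JointTrajectorySet(tuple(names), np.stack(arrays), timestamps, rate, valid)


def speed_profile_min_jerk(duration=1.0, fs=100.0, amplitude=1.0) -> ScalarSeries:
    """Bell-shaped minimum-jerk point-to-point speed profile."""
    t = np.arange(0.0, duration, 1.0 / fs)
    tau = t / duration
    v = amplitude * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    return ScalarSeries(v, t, "speed", np.ones(len(t), dtype=bool))


def random_rigid(rng):
    """Random proper rotation (QR-based, det +1) and translation."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-500, 500, 3)
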