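import numpy as np
import pytest

from vrphen.tracking import DEVICES, Device, Session


def session_from(head, left, right, dt=0.5, subject_id="S001"):
    """Build a Session from three coordinate lists/arrays of equal length."""
    head = np.asarray(head, dtype=float)
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    L = len(head)
    return Session(
        subject_id=subject_id,
        tracks={Device.HEAD: head, Device.LEFT_HAND: left, Device.RIGHT_HAND: right},
        dt=dt,
        duration=(L - 1) * dt,
    )


def random_session(rng, length=10, dt=0.5, scale=1.0):
    tracks = {
        d: rng.normal(0.0, scale, (length, 3)) for d in DEVICES
    }
    return Session(
        subject_id="R001", tracks=tracks, dt=dt, duration=(length - 1) * dt
    )


def tracks_as_lists(s):
    """Session tracks as plain nested lists keyed by device string (for oracles)."""
    return {d.value: s.tracks[d].tolist() for d in DEVICES}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stationary_session():
    L = 11
    head = np.tile([0.0, 1.5, 0.0], (L, 1))
    left = np.tile([-0.3, 1.2, 0.0], (L, 1))
    right = np.tile([0.3, 1.2, 0.0], (L, 1))
    return session_from(head, left, right)
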