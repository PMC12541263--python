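"""Seven kinematic variables summarizing a tracked session.

The variables fall into three families:

* velocity — average speed and acceleration of head and hand movement;
* spatial — total distance traveled, floor area occupied (convex hull of
  the head's floor-plane projection), and mean hand-to-head distance;
* frequency/duration — how often movement bouts start, and how long the
  participant stays still.

All features are computed from per-step Euclidean displacements on the
uniform grid. Two displacement thresholds parameterize the frequency and
duration family: ``threshold_1`` is the minimum per-step displacement to
count as movement, ``threshold_2`` the maximum displacement still
considered stationary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import shapely

from .tracking import DEVICES, Device, Session

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "FeatureError",
    "FEATURE_NAMES",
    "step_displacements",
    "average_speed",
    "acceleration",
    "total_distance",
    "area_occupied",
    "hand_head_distance",
    "movement_frequency",
    "time_spent_still",
    "extract_features",
]

FEATURE_NAMES: tuple[str, ...] = (
    "average_speed",
    "acceleration",
    "total_distance",
    "area_occupied",
    "hand_head_distance",
    "movement_frequency",
    "time_spent_still",
)


class FeatureError(ValueError):
    """Raised when a session cannot support a feature computation."""


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds for movement detection, in meters per grid step.

    ``threshold_1``: minimum displacement for a step to count as movement.
    ``threshold_2``: maximum displacement for a step to count as still.
    ``hull_min_points``: minimum distinct head floor-positions for a
    nonzero occupancy area.
    """

    threshold_1: float = 0.05
    threshold_2: float = 0.02
    hull_min_points: int = 3

    def __post_init__(self) -> None:
        if not (self.threshold_1 > 0 and self.threshold_2 > 0):
            raise ValueError("thresholds must be positive")
        if self.threshold_2 > self.threshold_1:
            raise ValueError("threshold_2 must not exceed threshold_1")
        if self.hull_min_points < 3:
            raise ValueError("hull_min_points must be at least 3")


@dataclass(frozen=True)
class FeatureVector:
    """The seven movement variables for one session.

    Units: m/s, m/s^2, m, m^2, m, events/min, s.
    """

    average_speed: float
    acceleration: float
    total_distance: float
    area_occupied: float
    hand_head_distance: float
    movement_frequency: float
    time_spent_still: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _check_session(s: Session, min_len: int = 1) -> None:
    if not s.is_complete:
        raise FeatureError("session has missing samples; validate it first")
    if s.length < min_len:
        raise FeatureError("session too short")


def step_displacements(s: Session, device: Device) -> np.ndarray:
    """Euclidean distance between consecutive grid positions of one device."""
    _check_session(s, min_len=2)
    track = s.tracks[Device(device)]
    return np.linalg.norm(np.diff(track, axis=0), axis=1)


def _max_step_displacement(s: Session) -> np.ndarray:
    """Per-step maximum displacement over the three devices."""
    return np.max([step_displacements(s, d) for d in DEVICES], axis=0)


def average_speed(s: Session) -> float:
    """Mean step speed (displacement / dt), averaged over the three devices.

    Exact summation keeps the result independent of device order, so
    relabeling the two hands cannot change the value even in the last bit.
    """
    _check_session(s, min_len=2)
    return math.fsum(
        math.fsum(step_displacements(s, d) / s.dt) / (s.length - 1) for d in DEVICES
    ) / 3.0


def acceleration(s: Session) -> float:
    """Mean magnitude of step-to-step speed change per unit time.

    Per device, consecutive step speeds v_k = d_k/dt give
    |v_{k+1} - v_k| / dt; these are averaged within and then across
    devices, yielding a nonnegative movement-intensity measure.
    """
    _check_session(s, min_len=3)
    vals = []
    for d in DEVICES:
        v = step_displacements(s, d) / s.dt
        vals.append(math.fsum(np.abs(np.diff(v)) / s.dt) / (len(v) - 1))
    return math.fsum(vals) / 3.0


def total_distance(s: Session) -> float:
    """Total path length summed over head and both hands."""
    _check_session(s, min_len=2)
    return math.fsum(math.fsum(step_displacements(s, d)) for d in DEVICES)


def area_occupied(s: Session, cfg: FeatureConfig | None = None) -> float:
    """Convex-hull area of the head's floor-plane (x, z) projection.

    Zero when fewer than ``hull_min_points`` distinct positions exist or
    when all positions are collinear.
    """
    cfg = cfg or FeatureConfig()
    _check_session(s, min_len=1)
    head = s.tracks[Device.HEAD]
    pts = np.unique(head[:, [0, 2]], axis=0)
    if len(pts) < cfg.hull_min_points:
        return 0.0
    # shapely's convex hull degrades to a segment/point for collinear input,
    # whose area is 0 as required
    return float(shapely.convex_hull(shapely.multipoints(pts)).area)


def hand_head_distance(s: Session) -> float:
    """Mean over time of the average of the two hand-to-head distances."""
    _check_session(s, min_len=1)
    head = s.tracks[Device.HEAD]
    d_left = np.linalg.norm(s.tracks[Device.LEFT_HAND] - head, axis=1)
    d_right = np.linalg.norm(s.tracks[Device.RIGHT_HAND] - head, axis=1)
    return float(np.mean((d_left + d_right) / 2.0))


def movement_frequency(s: Session, cfg: FeatureConfig | None = None) -> float:
    """Movement-bout onsets per minute.

    A step is "moving" when any device's displacement exceeds
    ``threshold_1``; an event is a transition into the moving state (the
    session start counts if it begins moving). The count is normalized
    by the spanned session time in minutes.
    """
    cfg = cfg or FeatureConfig()
    _check_session(s, min_len=2)
    moving = _max_step_displacement(s) > cfg.threshold_1
    onsets = int(moving[0]) + int(np.sum(moving[1:] & ~moving[:-1]))
    minutes = (s.length - 1) * s.dt / 60.0
    return float(onsets / minutes)


def time_spent_still(s: Session, cfg: FeatureConfig | None = None) -> float:
    """Total time, in seconds, of steps where no device moved beyond threshold_2."""
    cfg = cfg or FeatureConfig()
    _check_session(s, min_len=2)
    still = _max_step_displacement(s) <= cfg.threshold_2
    return float(np.sum(still) * s.dt)


def extract_features(s: Session, cfg: FeatureConfig | None = None) -> FeatureVector:
    """Assemble all seven variables for one session (deterministic)."""
    cfg = cfg or FeatureConfig()
    return FeatureVector(
        average_speed=average_speed(s),
        acceleration=acceleration(s),
        total_distance=total_distance(s),
        area_occupied=area_occupied(s, cfg),
        hand_head_distance=hand_head_distance(s),
        movement_frequency=movement_frequency(s, cfg),
        time_spent_still=time_spent_still(s, cfg),
    )
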