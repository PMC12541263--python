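"""Synthetic cohorts: tracked sessions plus questionnaire items.

A single latent "hyperkinesis" trait h drives both sides of the data:

* movement — a two-state (still/moving) Markov bout process on the
  sampling grid; while moving, the head advances toward random waypoints
  in a rectangular room at speed ``speed_base * exp(speed_loading * h)``;
  higher h makes still bouts end sooner and moving bouts last longer.
  Hands follow the head at a slowly wandering offset. Positional jitter
  and postural sway are added everywhere, and floor positions are
  clamped to the room.
* symptoms — each questionnaire item is an ordered-categorical draw
  whose latent location is ``item_loading * h + item_difficulty`` plus
  logistic noise; participant (self-report) noise is inflated relative
  to parent report, so parent scores track h more tightly.

Everything is reproducible from the config seed. A calibration helper
searches the item loading that yields a target feature-score
correlation, so effect-recovery studies can plant a known population
effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

from .tracking import DEVICES, Device, Session, grid_length
from . import features as _feat
from .features import FEATURE_NAMES, FeatureConfig, extract_features
from .scales import (
    ADHD_HYPERACTIVITY_ITEMS,
    ADHD_INATTENTION_ITEMS,
    INSTRUMENT_SPECS,
    RPQ_PROACTIVE_ITEMS,
    RPQ_REACTIVE_ITEMS,
    Informant,
    Instrument,
    ItemResponses,
    ScoreSet,
    score_subject,
)

import pandas as pd

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "simulate_trajectory",
    "simulate_items",
    "simulate_cohort",
    "calibrate_item_loading",
]

#: the five instrument/informant combinations collected per subject
RESPONSE_KEYS: tuple[tuple[Instrument, Informant], ...] = (
    (Instrument.ADHD_RS, Informant.PARENT),
    (Instrument.ARI, Informant.PARENT),
    (Instrument.ARI, Informant.PARTICIPANT),
    (Instrument.RPQ, Informant.PARENT),
    (Instrument.RPQ, Informant.PARTICIPANT),
)


def _default_difficulty() -> dict[str, float]:
    # chosen so that h=0 subjects land near mid-range symptom scores
    return {"ADHD_RS": -0.4, "ARI": -0.6, "RPQ": -1.0}


@dataclass(frozen=True)
class CohortConfig:
    """Simulation parameters for one synthetic cohort.

    The movement side is parameterized in meters and seconds; the
    bout-switching rates are logits of per-step transition
    probabilities, with loadings applied per unit of the latent trait h.
    """

    n: int = 45
    seed: int = 0
    dt: float = 0.5
    duration: float = 300.0
    room_half_x: float = 2.0
    room_half_z: float = 1.5
    trait_sd: float = 1.0
    speed_base: float = 0.35
    speed_loading: float = 0.35
    still_rate_base: float = -2.2  # logit P(leave still state) at h=0
    still_rate_loading: float = 0.6
    move_stop_base: float = -1.5  # logit P(leave moving state) at h=0
    move_stop_loading: float = -0.4
    hand_offset: float = 0.45
    noise_sd: float = 0.003
    sway_sd: float = 0.02  # head postural sway (vertical), stationary AR(1) SD
    hand_sway_sd: float = 0.02
    head_height: float = 1.25
    head_height_sd: float = 0.08
    item_loading: float = 0.46
    item_difficulty: dict[str, float] = field(default_factory=_default_difficulty)
    participant_noise_scale: float = 1.6

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.dt <= 0 or self.duration < 0:
            raise ValueError("dt must be positive and duration non-negative")
        if self.room_half_x <= 0 or self.room_half_z <= 0:
            raise ValueError("room half-widths must be positive")
        for name in ("trait_sd", "noise_sd", "sway_sd", "hand_sway_sd", "head_height_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.speed_base < 0 or self.hand_offset < 0:
            raise ValueError("speed_base and hand_offset must be non-negative")
        if self.participant_noise_scale <= 0:
            raise ValueError("participant_noise_scale must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """Sessions, item responses and the generative truth, aligned by subject."""

    sessions: list[Session]
    items: list[ItemResponses]
    truth: pd.DataFrame

    def items_for(self, subject_id: str) -> list[ItemResponses]:
        return [r for r in self.items if r.subject_id == subject_id]

    def score_sets(self, ari_items_in_total: int = 6) -> list[ScoreSet]:
        by_subject: dict[str, list[ItemResponses]] = {}
        for r in self.items:
            by_subject.setdefault(r.subject_id, []).append(r)
        return [
            score_subject(by_subject[s.subject_id], ari_items_in_total=ari_items_in_total)
            for s in self.sessions
        ]


def _ar1(white: np.ndarray, phi: float, axis: int = -1) -> np.ndarray:
    """AR(1) noise whose stationary SD equals the white-noise SD.

    The first sample is rescaled so the process is stationary from the
    start rather than building up from zero.
    """
    w = np.moveaxis(np.asarray(white, dtype=float), axis, -1).copy()
    scale = np.sqrt(1.0 - phi * phi)
    w[..., 0] /= scale
    out = lfilter([1.0], [1.0, -phi], w, axis=-1) * scale
    return np.moveaxis(out, -1, axis)


def _simulate_tracks(
    h: np.ndarray, cfg: CohortConfig, rng: np.random.Generator
) -> dict[Device, np.ndarray]:
    """Vectorized trajectory simulation; returns (n, L, 3) per device."""
    n = len(h)
    L = grid_length(cfg.duration, cfg.dt)
    hx, hz = cfg.room_half_x, cfg.room_half_z

    speed = cfg.speed_base * np.exp(cfg.speed_loading * h)
    p_go = expit(cfg.still_rate_base + cfg.still_rate_loading * h)
    p_stop = expit(cfg.move_stop_base + cfg.move_stop_loading * h)

    pos = rng.uniform([-hx / 2, -hz / 2], [hx / 2, hz / 2], (n, 2))
    waypoint = rng.uniform([-hx, -hz], [hx, hz], (n, 2))
    moving = np.zeros(n, dtype=bool)

    floor = np.empty((n, L, 2))
    floor[:, 0] = pos
    step_len = speed * cfg.dt
    for k in range(1, L):
        u = rng.random(n)
        moving = np.where(moving, u >= p_stop, u < p_go)
        delta = waypoint - pos
        dist = np.linalg.norm(delta, axis=1)
        reach = dist <= step_len
        direction = delta / np.maximum(dist, 1e-12)[:, None]
        advanced = np.where(
            reach[:, None], waypoint, pos + direction * step_len[:, None]
        )
        pos = np.where(moving[:, None], advanced, pos)
        fresh = rng.uniform([-hx, -hz], [hx, hz], (n, 2))
        waypoint = np.where((moving & reach)[:, None], fresh, waypoint)
        floor[:, k] = pos

    height = rng.normal(cfg.head_height, cfg.head_height_sd, n)
    sway = _ar1(rng.normal(0.0, cfg.sway_sd, (n, L)), 0.95, axis=1) if cfg.sway_sd > 0 else 0.0
    head = np.empty((n, L, 3))
    head[:, :, 0] = floor[:, :, 0]
    head[:, :, 1] = height[:, None] + sway
    head[:, :, 2] = floor[:, :, 1]
    head += rng.normal(0.0, cfg.noise_sd, (n, L, 3))
    np.clip(head[:, :, 0], -hx, hx, out=head[:, :, 0])
    np.clip(head[:, :, 2], -hz, hz, out=head[:, :, 2])

    tracks = {Device.HEAD: head}
    base_dirs = {
        Device.LEFT_HAND: np.array([-0.5, -0.7, 0.5]),
        Device.RIGHT_HAND: np.array([0.5, -0.7, 0.5]),
    }
    for dev, direction in base_dirs.items():
        offset = cfg.hand_offset * direction / np.linalg.norm(direction)
        wobble = (
            _ar1(rng.normal(0.0, cfg.hand_sway_sd, (n, L, 3)), 0.95, axis=1)
            if cfg.hand_sway_sd > 0
            else 0.0
        )
        jitter = rng.normal(0.0, cfg.noise_sd, (n, L, 3))
        tracks[dev] = head + offset + wobble + jitter
    return tracks


_CUTS = {2: np.array([-1.0, 1.0]), 3: np.array([-1.8, 0.0, 1.8])}


def _simulate_items_array(
    h: np.ndarray,
    instrument: Instrument,
    informant: Informant,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n, n_items) ordered-categorical responses for one instrument/informant."""
    instrument = Instrument(instrument)
    n_items, max_val = INSTRUMENT_SPECS[instrument]
    cuts = _CUTS[max_val]
    difficulty = cfg.item_difficulty[instrument.value]
    noise_scale = (
        cfg.participant_noise_scale
        if Informant(informant) is Informant.PARTICIPANT
        else 1.0
    )
    noise = rng.logistic(0.0, 1.0, (len(h), n_items)) * noise_scale
    latent = cfg.item_loading * h[:, None] + difficulty + noise
    return (latent[:, :, None] > cuts).sum(axis=2).astype(int)


def simulate_trajectory(h: float, cfg: CohortConfig, seed: int, subject_id: str = "S001") -> Session:
    """One subject's session at latent trait value ``h``."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    tracks = _simulate_tracks(np.array([float(h)]), cfg, rng)
    return Session(
        subject_id=subject_id,
        tracks={d: tracks[d][0] for d in DEVICES},
        dt=cfg.dt,
        duration=cfg.duration,
    )


def simulate_items(
    h: float,
    instrument: Instrument,
    informant: Informant,
    cfg: CohortConfig,
    seed: int,
    subject_id: str = "S001",
) -> ItemResponses:
    """One instrument/informant response record at latent trait ``h``."""
    cfg.validate()
    if Instrument(instrument) not in INSTRUMENT_SPECS:  # pragma: no cover
        raise ValueError(f"unknown instrument {instrument!r}")
    rng = np.random.default_rng(seed)
    arr = _simulate_items_array(np.array([float(h)]), instrument, informant, cfg, rng)
    return ItemResponses(
        instrument=Instrument(instrument),
        informant=Informant(informant),
        items=tuple(int(v) for v in arr[0]),
        subject_id=subject_id,
    )


def simulate_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Draw h_i ~ N(0, trait_sd^2) and emit sessions, items and truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    h = rng.normal(0.0, cfg.trait_sd, n)

    sessions: list[Session] = []
    if n > 0:
        tracks = _simulate_tracks(h, cfg, rng)
        sessions = [
            Session(
                subject_id=subject_ids[i],
                tracks={d: tracks[d][i] for d in DEVICES},
                dt=cfg.dt,
                duration=cfg.duration,
            )
            for i in range(n)
        ]

    items: list[ItemResponses] = []
    for instrument, informant in RESPONSE_KEYS:
        arr = _simulate_items_array(h, instrument, informant, cfg, rng)
        for i in range(n):
            items.append(
                ItemResponses(
                    instrument=instrument,
                    informant=informant,
                    items=tuple(int(v) for v in arr[i]),
                    subject_id=subject_ids[i],
                )
            )

    truth = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "h": h,
            "speed": cfg.speed_base * np.exp(cfg.speed_loading * h),
            "p_leave_still": expit(cfg.still_rate_base + cfg.still_rate_loading * h),
            "p_stop_moving": expit(cfg.move_stop_base + cfg.move_stop_loading * h),
        }
    )
    return SyntheticCohort(sessions=sessions, items=items, truth=truth)


# measure name -> (instrument, informant, 1-based item positions summed)
_MEASURE_SOURCES: dict[str, tuple[Instrument, Informant, tuple[int, ...]]] = {
    "adhd_hyperactivity": (Instrument.ADHD_RS, Informant.PARENT, ADHD_HYPERACTIVITY_ITEMS),
    "adhd_inattention": (Instrument.ADHD_RS, Informant.PARENT, ADHD_INATTENTION_ITEMS),
    "adhd_total": (Instrument.ADHD_RS, Informant.PARENT, tuple(range(1, 19))),
    "ari_parent": (Instrument.ARI, Informant.PARENT, tuple(range(1, 7))),
    "ari_participant": (Instrument.ARI, Informant.PARTICIPANT, tuple(range(1, 7))),
    "rpq_parent_reactive": (Instrument.RPQ, Informant.PARENT, RPQ_REACTIVE_ITEMS),
    "rpq_parent_proactive": (Instrument.RPQ, Informant.PARENT, RPQ_PROACTIVE_ITEMS),
    "rpq_parent_total": (Instrument.RPQ, Informant.PARENT, tuple(range(1, 24))),
    "rpq_participant_reactive": (Instrument.RPQ, Informant.PARTICIPANT, RPQ_REACTIVE_ITEMS),
    "rpq_participant_proactive": (Instrument.RPQ, Informant.PARTICIPANT, RPQ_PROACTIVE_ITEMS),
    "rpq_participant_total": (Instrument.RPQ, Informant.PARTICIPANT, tuple(range(1, 24))),
}


def feature_values(
    tracks: dict[Device, np.ndarray],
    feature: str,
    cfg: CohortConfig,
    fcfg: FeatureConfig | None = None,
) -> np.ndarray:
    """Evaluate one kinematic feature for every subject in a track stack."""
    if feature not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature!r}")
    fcfg = fcfg or FeatureConfig()
    op = getattr(_feat, feature)
    takes_cfg = feature in ("area_occupied", "movement_frequency", "time_spent_still")
    n = len(tracks[Device.HEAD])
    vals = np.empty(n)
    for i in range(n):
        s = Session(
            subject_id=f"S{i + 1:03d}",
            tracks={d: tracks[d][i] for d in DEVICES},
            dt=cfg.dt,
            duration=cfg.duration,
        )
        vals[i] = op(s, fcfg) if takes_cfg else op(s)
    return vals


def calibrate_item_loading(
    cfg: CohortConfig,
    target_r: float,
    feature: str = "average_speed",
    measure: str = "adhd_hyperactivity",
    n_probe: int = 3000,
    seed: int = 0,
    tol: float = 0.005,
    max_loading: float = 12.0,
) -> CohortConfig:
    """Find the item loading yielding a target feature-score correlation.

    A large probe cohort's kinematic feature is simulated once (it does
    not depend on the item loading); the loading is then bisected on the
    probe correlation between that feature and the requested score,
    holding the probe's random draws fixed so the objective is monotone.
    Raises if the target is unattainable even at ``max_loading``.
    """
    if feature not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature!r}")
    if measure not in _MEASURE_SOURCES:
        raise ValueError(f"unknown measure {measure!r}")
    cfg.validate()

    rng = np.random.default_rng(seed)
    h = rng.normal(0.0, cfg.trait_sd, n_probe)
    tracks = _simulate_tracks(h, cfg, rng)
    feat_vals = feature_values(tracks, feature, cfg)

    instrument, informant, positions = _MEASURE_SOURCES[measure]
    idx = np.array(positions) - 1

    def probe_r(loading: float) -> float:
        trial = replace(cfg, item_loading=loading)
        arr = _simulate_items_array(
            h, instrument, informant, trial, np.random.default_rng(seed + 1)
        )
        scores = arr[:, idx].sum(axis=1)
        if np.std(scores) == 0:
            return 0.0
        return float(np.corrcoef(feat_vals, scores)[0, 1])

    lo, hi = 1e-3, max_loading
    if probe_r(hi) < target_r:
        raise ValueError(
            f"target correlation {target_r} unattainable at item_loading <= {max_loading}"
        )
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        r = probe_r(mid)
        if abs(r - target_r) < tol:
            return replace(cfg, item_loading=mid)
        if r < target_r:
            lo = mid
        else:
            hi = mid
    return replace(cfg, item_loading=0.5 * (lo + hi))
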