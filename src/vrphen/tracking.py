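"""Data model and I/O for three-device 3D tracking logs.

A tracked session records the positions of a head-mounted display and two
hand controllers as (x, y, z) coordinates in meters, sampled on a uniform
time grid (default every 0.5 s over a 5-minute session). The coordinate
convention is y-up: the (x, z) plane is the floor, y is height. Raw log
rows are snapped to the grid on read; short tracking dropouts can be
repaired by linear interpolation during validation.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "Device",
    "DEVICES",
    "TrackingError",
    "Session",
    "ValidationReport",
    "grid_length",
    "read_tracking_log",
    "validate_session",
    "write_tracking_log",
]


class Device(str, Enum):
    """The three tracked devices."""

    HEAD = "head"
    LEFT_HAND = "left_hand"
    RIGHT_HAND = "right_hand"


DEVICES: tuple[Device, ...] = (Device.HEAD, Device.LEFT_HAND, Device.RIGHT_HAND)

_CSV_HEADER = ["t", "device", "x", "y", "z"]


class TrackingError(ValueError):
    """Raised for malformed or inconsistent tracking data."""


def grid_length(duration: float, dt: float) -> int:
    """Number of samples on the uniform grid: floor(duration/dt) + 1.

    The grid is inclusive of t=0 and of the last scheduled sample at or
    before ``duration``.
    """
    if dt <= 0:
        raise TrackingError("dt must be positive")
    if duration < 0:
        raise TrackingError("duration must be non-negative")
    return int(math.floor(duration / dt)) + 1


@dataclass
class Session:
    """One subject's tracked trial: three aligned position series.

    ``tracks`` maps each device to an array of shape (L, 3) holding
    (x, y, z) in meters on the shared grid of times ``k * dt``. Grid
    points with no observation are NaN until validation fills or
    rejects them.
    """

    subject_id: str
    tracks: dict[Device, np.ndarray]
    dt: float = 0.5
    duration: float = 300.0
    n_raw_dropped: int = 0

    def __post_init__(self) -> None:
        L = grid_length(self.duration, self.dt)
        for dev in DEVICES:
            if dev not in self.tracks:
                raise TrackingError(f"missing device '{dev.value}'")
            arr = np.asarray(self.tracks[dev], dtype=float)
            if arr.shape != (L, 3):
                raise TrackingError(
                    f"track for '{dev.value}' has shape {arr.shape}, expected ({L}, 3)"
                )
            self.tracks[dev] = arr

    @property
    def length(self) -> int:
        return grid_length(self.duration, self.dt)

    @property
    def grid_times(self) -> np.ndarray:
        return np.arange(self.length) * self.dt

    @property
    def is_complete(self) -> bool:
        return all(np.isfinite(self.tracks[d]).all() for d in DEVICES)

    def copy(self) -> "Session":
        return Session(
            subject_id=self.subject_id,
            tracks={d: self.tracks[d].copy() for d in DEVICES},
            dt=self.dt,
            duration=self.duration,
            n_raw_dropped=self.n_raw_dropped,
        )

    def equals(self, other: "Session") -> bool:
        """Exact equality of grid and coordinates (NaNs compare equal)."""
        if (self.subject_id, self.dt, self.duration) != (
            other.subject_id,
            other.dt,
            other.duration,
        ):
            return False
        return all(
            np.array_equal(self.tracks[d], other.tracks[d], equal_nan=True)
            for d in DEVICES
        )


@dataclass
class ValidationReport:
    """Outcome of gap handling on one session."""

    n_gaps_filled: int = 0
    n_samples_dropped: int = 0
    passed: bool = True
    messages: list[str] = field(default_factory=list)


def _snap_index(t: float, dt: float) -> int:
    # nearest grid index; exact midpoints resolve toward the earlier sample
    return int(math.ceil(t / dt - 0.5))


def _iter_rows_csv(path: Path):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TrackingError(f"{path}: no samples") from None
        if [h.strip() for h in header] != _CSV_HEADER:
            raise TrackingError(
                f"{path}: line 1: expected header {','.join(_CSV_HEADER)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise TrackingError(f"{path}: line {lineno}: expected 5 fields")
            yield lineno, row[0], row[1], row[2], row[3], row[4]


def _iter_rows_jsonl(path: Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                yield lineno, obj["t"], obj["device"], obj["x"], obj["y"], obj["z"]
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise TrackingError(f"{path}: line {lineno}: unreadable row ({exc})") from None


def read_tracking_log(
    path: str | Path,
    dt: float = 0.5,
    duration: float = 300.0,
    subject_id: str | None = None,
) -> Session:
    """Parse a tracking log (CSV or JSON-lines) onto the uniform grid.

    Raw timestamps are snapped to the nearest grid time (ties toward the
    earlier sample); when several rows land on the same (device, grid
    time) the last one wins; rows outside the grid are dropped and
    counted in ``Session.n_raw_dropped``. Grid points never observed are
    left as NaN for :func:`validate_session` to handle.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem

    rows = (
        _iter_rows_jsonl(path)
        if path.suffix.lower() in {".jsonl", ".ndjson", ".json"}
        else _iter_rows_csv(path)
    )

    L = grid_length(duration, dt)
    tracks = {d: np.full((L, 3), np.nan) for d in DEVICES}
    last_t: dict[Device, float] = {}
    n_rows = 0
    n_dropped = 0

    for lineno, t_raw, dev_raw, x_raw, y_raw, z_raw in rows:
        try:
            t = float(t_raw)
            xyz = (float(x_raw), float(y_raw), float(z_raw))
        except (TypeError, ValueError):
            raise TrackingError(f"{path}: line {lineno}: unreadable row") from None
        try:
            dev = Device(str(dev_raw).strip())
        except ValueError:
            raise TrackingError(
                f"{path}: line {lineno}: unknown device {dev_raw!r}"
            ) from None
        if not all(math.isfinite(v) for v in (t, *xyz)) or t < 0:
            raise TrackingError(
                f"{path}: line {lineno}: non-finite or negative value"
            )
        if dev in last_t and t < last_t[dev]:
            raise TrackingError(
                f"{path}: line {lineno}: non-monotone timestamps for device "
                f"'{dev.value}'"
            )
        last_t[dev] = t
        n_rows += 1
        k = _snap_index(t, dt)
        if 0 <= k < L:
            tracks[dev][k] = xyz
        else:
            n_dropped += 1

    if n_rows == 0:
        raise TrackingError(f"{path}: no samples")
    for dev in DEVICES:
        if dev not in last_t:
            raise TrackingError(f"{path}: missing device '{dev.value}'")

    return Session(
        subject_id=subject_id,
        tracks=tracks,
        dt=dt,
        duration=duration,
        n_raw_dropped=n_dropped,
    )


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True as (start, stop) half-open index pairs."""
    runs = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return runs
    start = prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((start, prev + 1))
            start = i
        prev = i
    runs.append((start, prev + 1))
    return runs


def validate_session(s: Session, max_gap: int = 2) -> tuple[Session, ValidationReport]:
    """Fill short tracking gaps, reject long or boundary ones.

    Interior runs of at most ``max_gap`` consecutive missing grid samples
    per device are filled by per-coordinate linear interpolation between
    the flanking observations. Longer gaps, or missing samples at the
    session boundaries (which have no flank to interpolate from), fail
    validation. Validating an already-complete session is the identity.
    """
    out = s.copy()
    report = ValidationReport(n_samples_dropped=s.n_raw_dropped)

    for dev in DEVICES:
        arr = out.tracks[dev]
        missing = np.isnan(arr).any(axis=1)
        if not missing.any():
            continue
        if missing.all():
            report.passed = False
            report.messages.append(f"{dev.value}: no samples at all")
            continue
        for start, stop in _missing_runs(missing):
            gap = stop - start
            t0, t1 = start * s.dt, (stop - 1) * s.dt
            if start == 0 or stop == len(missing):
                report.passed = False
                report.messages.append(
                    f"{dev.value}: missing samples at session boundary "
                    f"(t={t0:g}-{t1:g} s) cannot be interpolated"
                )
            elif gap > max_gap:
                report.passed = False
                report.messages.append(
                    f"{dev.value}: gap of {gap} samples (t={t0:g}-{t1:g} s) "
                    f"exceeds max_gap={max_gap}"
                )
            else:
                lo, hi = start - 1, stop  # flanking observed samples
                for k in range(start, stop):
                    w = (k - lo) / (hi - lo)
                    arr[k] = (1.0 - w) * arr[lo] + w * arr[hi]
                report.n_gaps_filled += 1

    if not report.passed:
        # leave unfillable sessions untouched for inspection
        return s, report
    return out, report


def write_tracking_log(s: Session, path: str | Path) -> None:
    """Write a session as CSV at full float precision.

    Coordinates are serialized with ``repr``, whose shortest round-trip
    representation guarantees read(write(s)) == s bit-exactly. Grid
    points that are still missing (NaN) are skipped.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for k in range(s.length):
            t = k * s.dt
            for dev in DEVICES:
                row = s.tracks[dev][k]
                if np.isnan(row).any():
                    continue
                writer.writerow([repr(float(t)), dev.value] + [repr(float(v)) for v in row])
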