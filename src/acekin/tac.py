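"""Time-activity curves, frame schedules, and resampling.

Dynamic PET data arrive as framed time-activity curves (TACs): one activity
value (in SUV) per acquisition frame, on a schedule of contiguous frames of
varying duration.  Kinetic analysis works on a uniform 1-second grid, so
this module provides the framed container (:class:`TimeActivityCurve`), the
uniform container (:class:`SampledCurve`), CSV round-trip I/O, and the
frame -> grid interpolation used throughout the pipeline.

Conventions: time is kept internally in seconds; a frame's value is
attributed to its mid-time for interpolation; a (0, 0) anchor is prepended
so the grid is defined before the first frame mid-time (pre-bolus activity
is zero).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "SampledCurve",
    "default_schedule",
    "read_tac",
    "write_tac",
    "total_duration",
    "resample_1s",
    "frame_average",
    "auc",
]


class TacFormatError(ValueError):
    """Raised when a TAC file is malformed (missing/garbled columns)."""


class TacValidationError(ValueError):
    """Raised when frame-schedule or curve invariants are violated."""


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames.

    Parameters
    ----------
    frame_start : array-like
        Frame start times in seconds, strictly increasing, starting at 0.
    frame_duration : array-like
        Frame durations in seconds, all > 0; frame i must end exactly where
        frame i+1 starts.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or dur.ndim != 1 or start.size != dur.size:
            raise TacValidationError("frame_start and frame_duration must be 1-D and equal length")
        if start.size == 0:
            raise TacValidationError("schedule must contain at least one frame")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(dur)):
            raise TacValidationError("schedule times must be finite")
        if np.any(dur <= 0):
            raise TacValidationError("all frame durations must be > 0")
        if np.any(np.diff(start) <= 0):
            raise TacValidationError("frame starts must be strictly increasing")
        # contiguity: each frame ends where the next begins
        ends = start[:-1] + dur[:-1]
        if not np.allclose(ends, start[1:], rtol=0.0, atol=1e-9):
            raise TacValidationError("frames must be contiguous (no gaps or overlaps)")

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-times in seconds."""
        return self.frame_start + 0.5 * self.frame_duration


def default_schedule() -> FrameSchedule:
    """The acquisition schedule used throughout: 24 x 10 s, 12 x 30 s, 4 x 300 s (30 min)."""
    dur = np.concatenate([np.full(24, 10.0), np.full(12, 30.0), np.full(4, 300.0)])
    start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    return FrameSchedule(start, dur)


@dataclass
class TimeActivityCurve:
    """A framed activity curve in SUV on a :class:`FrameSchedule`."""

    schedule: FrameSchedule
    values: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.schedule.n_frames:
            raise TacValidationError("values length must equal the number of frames")
        if not np.all(np.isfinite(self.values)):
            raise TacValidationError("TAC values must be finite")


@dataclass
class SampledCurve:
    """A curve on the uniform 1-second grid t = 0, 1, ..., T."""

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise TacValidationError("t and y must be 1-D and equal length")
        if self.t.size < 2 or self.t[0] != 0.0 or not np.allclose(np.diff(self.t), 1.0):
            raise TacValidationError("grid must be uniform 1-s spacing starting at 0")

    @property
    def end(self) -> float:
        return float(self.t[-1])

    def copy_with(self, y: np.ndarray) -> "SampledCurve":
        return SampledCurve(self.t.copy(), np.asarray(y, dtype=float))


def grid_1s(total_s: float) -> np.ndarray:
    """Uniform 1-s grid covering [0, total_s]."""
    return np.arange(0.0, float(total_s) + 0.5, 1.0)


def total_duration(schedule: FrameSchedule) -> float:
    """Total scan duration in seconds (sum of frame durations)."""
    return float(np.sum(schedule.frame_duration))


# ---------------------------------------------------------------- CSV I/O

_COLUMNS = ["frame_start_s", "frame_duration_s", "value_suv"]


def write_tac(curve: TimeActivityCurve, path) -> None:
    """Write a TAC as CSV with '#key: value' metadata header lines."""
    with open(path, "w") as fh:
        if curve.label:
            fh.write(f"#label: {curve.label}\n")
        for key, val in curve.meta.items():
            fh.write(f"#{key}: {val}\n")
        fh.write(",".join(_COLUMNS) + "\n")
        for start, dur, val in zip(
            curve.schedule.frame_start, curve.schedule.frame_duration, curve.values
        ):
            # shortest round-trip float repr keeps read_tac bit-exact
            fh.write(f"{float(start)!r},{float(dur)!r},{float(val)!r}\n")


def read_tac(path, dialect: str = "csv") -> TimeActivityCurve:
    """Read a TAC CSV (columns frame_start_s, frame_duration_s, value_suv).

    Lines starting with '#' are parsed as 'key: value' metadata.
    """
    if dialect not in ("csv", "tsv"):
        raise TacFormatError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    meta: dict = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, val = stripped.partition(":")
                    meta[key.strip()] = val.strip()
            else:
                body.write(line)
    body.seek(0)
    try:
        df = pd.read_csv(body, sep=sep, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise TacFormatError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TacFormatError(f"{path}: missing required columns {missing}")
    label = meta.pop("label", "")
    schedule = FrameSchedule(df["frame_start_s"].to_numpy(), df["frame_duration_s"].to_numpy())
    return TimeActivityCurve(schedule, df["value_suv"].to_numpy(), label=label, meta=meta)


# ----------------------------------------------------- resampling and AUC


def resample_1s(curve: TimeActivityCurve) -> SampledCurve:
    """Linearly interpolate a framed TAC onto the 1-s grid.

    Values are attributed to frame mid-times; a (0, 0) anchor is prepended,
    and the last mid-time value is extended to the scan end.
    """
    if curve.schedule.n_frames < 2:
        raise TacValidationError("resampling requires at least 2 frames")
    mids = curve.schedule.mid_times
    t = grid_1s(total_duration(curve.schedule))
    xp = np.concatenate([[0.0], mids])
    yp = np.concatenate([[0.0], curve.values])
    y = np.interp(t, xp, yp)  # constant extension past the last mid-time
    return SampledCurve(t, y)


def frame_average(curve: SampledCurve, schedule: FrameSchedule, label: str = "") -> TimeActivityCurve:
    """Project a 1-s curve onto a frame schedule by averaging within frames.

    PET frames measure time-averaged activity; the frame value is the mean
    of the continuous curve over the frame interval (trapezoidal mean on the
    1-s grid).
    """
    if total_duration(schedule) > curve.end + 1e-9:
        raise TacValidationError("schedule extends beyond the sampled curve")
    vals = np.empty(schedule.n_frames)
    for i, (s, d) in enumerate(zip(schedule.frame_start, schedule.frame_duration)):
        i0, i1 = int(round(s)), int(round(s + d))
        vals[i] = np.trapezoid(curve.y[i0 : i1 + 1], curve.t[i0 : i1 + 1]) / (i1 - i0)
    return TimeActivityCurve(schedule, vals, label=label)


def auc(curve: SampledCurve, t0: float, t1: float) -> float:
    """Trapezoidal area under the curve over [t0, t1] seconds, in SUV*min."""
    if not (0.0 <= t0 < t1 <= curve.end):
        raise ValueError(f"window [{t0}, {t1}] outside grid [0, {curve.end}]")
    # integrate on the native grid, splitting edge cells exactly
    t = curve.t
    y = curve.y
    tt = np.union1d(t[(t >= t0) & (t <= t1)], [t0, t1])
    yy = np.interp(tt, t, y)
    return float(np.trapezoid(yy, tt)) / 60.0
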