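"""Preprocessing of raw cyclic angle recordings.

A continuous flexion-extension recording is divided into complete cycles
(minimum to minimum of the angle signal, i.e. maximum flexion to maximum
flexion), the first and last cycles are discarded, each remaining cycle is
time-normalized to [0, 1] by cubic-spline resampling, and the kept cycles
are averaged pointwise into one curve per observation.  Velocity and
acceleration follow by differentiating the spline representation with
respect to real time, which requires carrying the mean cycle duration.

Cubic splines with natural end conditions are used throughout: acceleration
needs a twice-differentiable representation, and finite differences on a
100-point grid would amplify measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .curves_io import RESPONSE_UNITS, CurveSet, TimeGrid

_NEXT_RESPONSE = {"angle": "velocity", "velocity": "acceleration"}


@dataclass
class RawRecording:
    """A continuous angle recording: time in seconds, angle in degrees."""

    time: np.ndarray
    angle: np.ndarray
    observation_id: str

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.time.shape != self.angle.shape or self.time.ndim != 1:
            raise ValueError("time and angle must be 1-D arrays of equal length")
        if self.time.size < 3:
            raise ValueError("a recording needs at least 3 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.angle))):
            raise ValueError("recording contains missing values")


@dataclass(frozen=True)
class CycleSegment:
    """Half-open sample index range [start_index, end_index) of one cycle.

    The boundary sample at ``end_index`` (the shared minimum) is included
    when resampling so consecutive cycles tile the recording.
    """

    start_index: int
    end_index: int
    duration: float

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def segment_cycles(rec: RawRecording, min_prominence: float | None = None) -> list[CycleSegment]:
    """Divide a recording into complete minimum-to-minimum cycles.

    Cycle boundaries are local minima of the angle signal with prominence at
    least ``min_prominence`` degrees (default: 20% of the recording's angle
    range).  At least 3 complete cycles must be found, otherwise discarding
    the first and last would leave nothing.
    """
    rng = float(np.ptp(rec.angle))
    if min_prominence is None:
        min_prominence = 0.2 * rng
    if rng == 0.0:
        raise ValueError(f"recording {rec.observation_id!r}: constant signal, no cycles found")
    minima, _ = find_peaks(-rec.angle, prominence=min_prominence)
    segments = []
    for a, b in zip(minima[:-1], minima[1:]):
        segments.append(CycleSegment(int(a), int(b), float(rec.time[b] - rec.time[a])))
    if len(segments) < 3:
        raise ValueError(
            f"recording {rec.observation_id!r}: only {len(segments)} complete cycles detected; "
            "at least 3 are required to discard the first and last"
        )
    return segments


def discard_edge_cycles(segments: Sequence[CycleSegment]) -> list[CycleSegment]:
    """Drop the first and last cycles (movement onset/termination artifacts)."""
    if len(segments) < 3:
        raise ValueError("need at least 3 cycles to discard the first and last")
    return list(segments[1:-1])


def normalize_cycle(rec: RawRecording, seg: CycleSegment, grid: TimeGrid) -> np.ndarray:
    """Time-normalize one cycle onto the grid by cubic-spline resampling.

    Grid point s maps linearly to real time ``t_start + s * duration``; the
    spline interpolates the raw samples of the segment (boundary sample
    included).
    """
    sl = slice(seg.start_index, seg.end_index + 1)
    t, y = rec.time[sl], rec.angle[sl]
    if t.size < 4:
        raise ValueError("segment has fewer than 4 samples; cubic spline needs 4")
    spline = CubicSpline(t, y, bc_type="natural")
    return spline(t[0] + grid.points * (t[-1] - t[0]))


def average_cycles(curves: Sequence[np.ndarray]) -> np.ndarray:
    """Pointwise arithmetic mean of cycles resampled on a common grid."""
    if len(curves) < 1:
        raise ValueError("need at least one cycle to average")
    stack = np.asarray(curves, dtype=float)
    if stack.ndim != 2:
        raise ValueError("cycles must share a common grid")
    return stack.mean(axis=0)


def preprocess_recording(
    rec: RawRecording, grid: TimeGrid, min_prominence: float | None = None
) -> tuple[np.ndarray, float]:
    """Full per-observation pipeline: segment, discard edges, normalize, average.

    Returns the mean normalized angle cycle and the mean cycle duration in
    seconds (needed to express derivatives in real-time units).
    """
    kept = discard_edge_cycles(segment_cycles(rec, min_prominence))
    curves = [normalize_cycle(rec, seg, grid) for seg in kept]
    mean_duration = float(np.mean([seg.duration for seg in kept]))
    return average_cycles(curves), mean_duration


def preprocess_recordings(
    recs: Sequence[RawRecording], grid: TimeGrid, min_prominence: float | None = None
) -> tuple[CurveSet, np.ndarray]:
    """Apply :func:`preprocess_recording` to every recording.

    Returns the angle :class:`CurveSet` and the per-observation mean cycle
    durations (seconds).
    """
    rows, durations, ids = [], [], []
    for rec in recs:
        curve, dur = preprocess_recording(rec, grid, min_prominence)
        rows.append(curve)
        durations.append(dur)
        ids.append(rec.observation_id)
    return CurveSet(grid, np.asarray(rows), "angle", ids), np.asarray(durations)


def differentiate_curves(cs: CurveSet, cycle_durations: np.ndarray) -> CurveSet:
    """Differentiate each curve with respect to real time via its spline.

    On the normalized time s = t / duration the chain rule gives
    d/dt = (1/duration) d/ds, so angle (deg) becomes velocity (deg/s) and
    velocity becomes acceleration (deg/s2).  ``cycle_durations`` holds one
    duration in seconds per observation.
    """
    if cs.response_label not in _NEXT_RESPONSE:
        raise ValueError("can only differentiate angle (to velocity) or velocity (to acceleration)")
    durations = np.asarray(cycle_durations, dtype=float)
    if durations.shape != (cs.n,):
        raise ValueError(f"need one cycle duration per observation ({cs.n}), got {durations.shape}")
    if not np.all(np.isfinite(durations)) or np.any(durations <= 0):
        raise ValueError("cycle durations must be positive and finite")
    out = np.empty_like(cs.values)
    for i in range(cs.n):
        spline = CubicSpline(cs.grid.points, cs.values[i], bc_type="natural")
        out[i] = spline.derivative()(cs.grid.points) / durations[i]
    label = _NEXT_RESPONSE[cs.response_label]
    return CurveSet(cs.grid, out, label, cs.observation_ids, RESPONSE_UNITS[label])


def read_raw_recordings(path: str | Path) -> list[RawRecording]:
    """Read long-format raw recordings (columns id, time_s, angle_deg)."""
    df = pd.read_csv(path, dtype={"id": str})
    required = ["id", "time_s", "angle_deg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    recs = []
    for obs_id, group in df.groupby("id", sort=False):
        recs.append(
            RawRecording(
                group["time_s"].to_numpy(dtype=float),
                group["angle_deg"].to_numpy(dtype=float),
                str(obs_id),
            )
        )
    return recs


def write_raw_recordings(recs: Sequence[RawRecording], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"id": rec.observation_id, "time_s": rec.time, "angle_deg": rec.angle})
        for rec in recs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
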