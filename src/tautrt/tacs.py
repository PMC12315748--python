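"""Frame schedules, time-activity curves, and gap-aware time integration.

All times are in minutes and activity concentrations in kBq/mL throughout the
package. A frame's stored value is the *time average* of the underlying
continuous concentration over the frame (reconstructed-frame semantics), not
an instantaneous sample. Acquisition breaks (gaps between consecutive frames)
are bridged, for integration purposes, by the straight line through the
midpoints of the two adjacent frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "ScanMeta",
    "mk6240_frame_schedule",
    "frames_in_window",
    "cumulative_integral",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered PET frame timing: start/end of each frame in minutes.

    Frames must be non-overlapping and strictly ordered; gaps between
    consecutive frames (mid-scan breaks) are allowed.
    """

    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.ndim != 1 or starts.shape != ends.shape or starts.size == 0:
            raise ValueError("starts and ends must be equal-length 1-D arrays")
        if np.any(ends <= starts):
            raise ValueError("every frame must have end > start")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(starts[1:] < ends[:-1] - 1e-9):
            raise ValueError("frames must not overlap")

    @property
    def n_frames(self) -> int:
        return self.starts.size

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def total_span(self) -> float:
        """Time of the last frame end (minutes post-injection)."""
        return float(self.ends[-1])

    def gaps(self) -> list[tuple[float, float]]:
        """Intervals (minutes) between consecutive frames not covered by data."""
        out = []
        for i in range(self.n_frames - 1):
            if self.starts[i + 1] > self.ends[i] + 1e-9:
                out.append((float(self.ends[i]), float(self.starts[i + 1])))
        return out

    def to_json(self) -> str:
        return json.dumps([[s, e] for s, e in zip(self.starts, self.ends)])

    @classmethod
    def from_json(cls, text: str) -> "FrameSchedule":
        pairs = json.loads(text)
        arr = np.asarray(pairs, dtype=float)
        return cls(arr[:, 0], arr[:, 1])


@dataclass(frozen=True)
class TimeActivityCurve:
    """Regional activity concentration per frame (kBq/mL) on a schedule."""

    schedule: FrameSchedule
    values: np.ndarray
    region: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"values length {values.size} != frame count {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("TAC values must be finite")


@dataclass(frozen=True)
class ScanMeta:
    """Per-scan metadata needed for SUV normalization."""

    subject_id: str
    session: str = "test"  # "test" | "retest"
    group: str = "oCN"  # "yCN" | "oCN" | "AD"
    injected_dose_mbq: float = 185.0
    body_weight_kg: float = 74.0

    def __post_init__(self) -> None:
        if self.session not in ("test", "retest"):
            raise ValueError(f"unknown session {self.session!r}")
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")


# Acquisition frame durations in seconds: 29 frames over 0-65 min, then a
# 15-min break, then 8 x 300 s frames over 80-120 min (37 frames total).
_SEGMENT1_S = [10] * 6 + [20] * 6 + [30] * 2 + [60] * 2 + [120] * 2 + [300] * 11
_SEGMENT2_S = [300] * 8


def mk6240_frame_schedule() -> FrameSchedule:
    """The two-segment 37-frame dynamic schedule used for [18F]MK-6240.

    Segment 1 (29 frames) covers 0-65 min: 6x10 s, 6x20 s, 2x30 s, 2x60 s,
    2x120 s, 11x300 s. After a 15-min break, segment 2 (8x300 s) covers
    80-120 min.
    """
    d1 = np.asarray(_SEGMENT1_S, dtype=float) / 60.0
    starts1 = np.concatenate([[0.0], np.cumsum(d1)[:-1]])
    ends1 = np.cumsum(d1)
    d2 = np.asarray(_SEGMENT2_S, dtype=float) / 60.0
    starts2 = 80.0 + np.concatenate([[0.0], np.cumsum(d2)[:-1]])
    ends2 = 80.0 + np.cumsum(d2)
    return FrameSchedule(np.concatenate([starts1, starts2]), np.concatenate([ends1, ends2]))


def frames_in_window(schedule: FrameSchedule, t0: float, t1: float) -> np.ndarray:
    """Indices of frames fully contained in [t0, t1] minutes.

    Raises ValueError if the window contains no complete frame (e.g. the
    65-80 min acquisition break).
    """
    if t0 >= t1:
        raise ValueError(f"window start {t0} must precede end {t1}")
    eps = 1e-9
    idx = np.flatnonzero((schedule.starts >= t0 - eps) & (schedule.ends <= t1 + eps))
    if idx.size == 0:
        raise ValueError(f"no frames fully contained in window [{t0}, {t1}] min")
    return idx


def _gap_line(tac: TimeActivityCurve, i: int) -> tuple[float, float]:
    """Slope/anchor of the midpoint-interpolation line bridging the gap after frame i."""
    sched = tac.schedule
    m0, m1 = sched.midpoints[i], sched.midpoints[i + 1]
    v0, v1 = tac.values[i], tac.values[i + 1]
    slope = (v1 - v0) / (m1 - m0)
    return v0, slope  # c(t) = v0 + slope * (t - m0)


def _gap_integral(tac: TimeActivityCurve, i: int, a: float, b: float) -> float:
    """Integral of the bridging line over [a, b] within the gap after frame i."""
    v0, slope = _gap_line(tac, i)
    m0 = tac.schedule.midpoints[i]
    return v0 * (b - a) + 0.5 * slope * ((b - m0) ** 2 - (a - m0) ** 2)


def cumulative_integral(tac: TimeActivityCurve, t) -> float | np.ndarray:
    """Integral of the TAC from time 0 to ``t`` (kBq*min/mL).

    Each frame contributes value x duration (the frame value is the mean over
    the frame); gaps between frames are bridged by linear interpolation
    between the midpoints of the adjacent frames. Before the first frame
    start (if nonzero) the first frame value is extended as a constant.

    ``t`` may be a scalar or an array; all entries must lie in
    [0, last frame end].
    """
    sched = tac.schedule
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < -1e-9) or np.any(t_arr > sched.total_span + 1e-9):
        raise ValueError(
            f"integration time outside scan span [0, {sched.total_span}] min"
        )

    # Cumulative integral at each frame start and end.
    n = sched.n_frames
    cum_start = np.empty(n)
    cum_end = np.empty(n)
    cum_start[0] = sched.starts[0] * tac.values[0]  # constant extension pre-scan
    for i in range(n):
        cum_end[i] = cum_start[i] + tac.values[i] * sched.durations[i]
        if i + 1 < n:
            gap = sched.starts[i + 1] - sched.ends[i]
            if gap > 1e-9:
                cum_start[i + 1] = cum_end[i] + _gap_integral(
                    tac, i, sched.ends[i], sched.starts[i + 1]
                )
            else:
                cum_start[i + 1] = cum_end[i]

    out = np.empty_like(t_arr)
    for j, tj in enumerate(t_arr):
        tj = min(max(tj, 0.0), sched.total_span)
        i = int(np.searchsorted(sched.ends, tj, side="left"))
        i = min(i, n - 1)
        if tj >= sched.starts[i]:  # inside frame i
            out[j] = cum_start[i] + tac.values[i] * (tj - sched.starts[i])
        elif i == 0:  # before first frame: constant extension
            out[j] = tac.values[0] * tj
        else:  # inside the gap after frame i-1
            out[j] = cum_end[i - 1] + _gap_integral(tac, i - 1, sched.ends[i - 1], tj)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def tacs_to_frame(tacs: dict[str, TimeActivityCurve]):
    """Tidy table (frame_start, frame_end, region, value) for a set of TACs."""
    import pandas as pd

    rows = []
    for name, tac in tacs.items():
        sched = tac.schedule
        for s, e, v in zip(sched.starts, sched.ends, tac.values):
            rows.append({"frame_start": s, "frame_end": e, "region": name, "value": v})
    return pd.DataFrame(rows)
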