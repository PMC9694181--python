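"""Turn segmentation and turning metrics from head yaw.

Heading is taken from the recorded quaternions (yaw about the vertical
axis), unwrapped so a continuous rotation never jumps across ±180°, and
low-pass filtered. A turn is a maximal interval where the absolute yaw rate
stays above a threshold, with hysteresis on the offset so a turn is not
chopped by brief dips; intervals whose net heading change is below a minimum
angle (e.g. obstacle-course sidesteps) are discarded, and same-direction
events separated by a short gap are merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .gait_engine import _sosfiltfilt
from .kinematics_io import KinematicsTrace, TraceValidationError

__all__ = [
    "TurnEvent",
    "TurnSummary",
    "heading_series",
    "segment_turns",
    "turn_summary",
    "analyze_turns",
]

#: yaw-rate onset threshold for a turn, deg/s
TURN_RATE_THRESHOLD = 15.0
#: offset hysteresis: a turn ends when |rate| falls below this fraction of threshold
TURN_OFFSET_FRACTION = 0.5
#: minimum net heading change for a kept turn, degrees
MIN_TURN_ANGLE = 45.0
#: low-pass cutoff applied to the unwrapped yaw, Hz
YAW_LOWPASS_HZ = 1.5
#: same-direction events closer than this are merged, s
TURN_MERGE_GAP_S = 0.3


@dataclass(frozen=True)
class TurnEvent:
    """One detected turn; magnitude is signed (+ = left)."""

    t_on: float
    t_off: float
    magnitude: float      # degrees, signed
    mean_velocity: float  # deg/s, unsigned
    peak_velocity: float  # deg/s, unsigned

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on

    @property
    def direction(self) -> str:
        return "left" if self.magnitude > 0 else "right"


@dataclass(frozen=True)
class TurnSummary:
    """Module-level turning metrics; NaN sentinels when no turns occurred."""

    n_turns: int
    mean_turn_time: float      # s
    avg_turn_velocity: float   # deg/s, mean of per-turn mean velocities
    peak_turn_velocity: float  # deg/s, max over per-turn peaks


def heading_series(
    trace: KinematicsTrace,
    lowpass_hz: float = YAW_LOWPASS_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Unwrapped, low-pass-filtered yaw in degrees with its time base.

    Yaw is the angle of the rotated forward axis about vertical:
    ``atan2(f_x, f_z)`` where ``f = R @ [0, 0, 1]``; positive yaw is a left
    turn in the package's Y-up convention.
    """
    norms = np.linalg.norm(trace.quat, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        i = int(np.argmax(np.abs(norms - 1.0) > 1e-6))
        raise TraceValidationError(f"non-unit quaternion at row {i} (norm {norms[i]:.6f})")
    # scipy uses scalar-last ordering
    rot = Rotation.from_quat(trace.quat[:, [1, 2, 3, 0]])
    fwd = rot.apply(np.array([0.0, 0.0, 1.0]))
    yaw = np.unwrap(np.arctan2(fwd[:, 0], fwd[:, 2]))
    yaw_deg = np.degrees(yaw)
    if lowpass_hz is not None and yaw_deg.shape[0] > 24:
        fs = 1.0 / float(np.median(np.diff(trace.t)))
        # first-order (zero-phase) on purpose: higher orders ring on the
        # plateau of a fast turn and bias the recovered peak rate upward
        yaw_deg = _sosfiltfilt(yaw_deg, fs, lowpass_hz, "lowpass", order=1)
    return trace.t.copy(), yaw_deg


def _yaw_rate(t: np.ndarray, yaw: np.ndarray) -> np.ndarray:
    """Central-difference yaw rate, deg/s."""
    return np.gradient(yaw, t)


def segment_turns(
    t: np.ndarray,
    yaw: np.ndarray,
    rate_threshold: float = TURN_RATE_THRESHOLD,
    min_angle: float = MIN_TURN_ANGLE,
    merge_gap: float = TURN_MERGE_GAP_S,
) -> list[TurnEvent]:
    """Segment a yaw series into turn events.

    Onset when ``|yaw rate|`` rises to ``rate_threshold``; offset when it
    falls below half the threshold (hysteresis). Events with net angle below
    ``min_angle`` are dropped; same-direction events separated by less than
    ``merge_gap`` seconds are merged before the angle test.
    """
    if t[-1] - t[0] < 1.0:
        raise ValueError("turn segmentation needs at least 1 s of data")
    rate = _yaw_rate(t, yaw)
    off_threshold = TURN_OFFSET_FRACTION * rate_threshold

    # raw above-threshold intervals with hysteresis
    raw: list[tuple[int, int]] = []
    i, n = 0, len(t)
    while i < n:
        if abs(rate[i]) >= rate_threshold:
            j = i
            while j + 1 < n and abs(rate[j + 1]) >= off_threshold:
                j += 1
            raw.append((i, j))
            i = j + 1
        else:
            i += 1

    def _event(i0: int, i1: int) -> TurnEvent:
        dur = float(t[i1] - t[i0])
        mag = float(yaw[i1] - yaw[i0])
        peak = float(np.max(np.abs(rate[i0:i1 + 1])))
        mean = abs(mag) / dur if dur > 0 else 0.0
        return TurnEvent(t_on=float(t[i0]), t_off=float(t[i1]),
                         magnitude=mag, mean_velocity=mean, peak_velocity=peak)

    # merge same-direction neighbours separated by a short gap
    merged: list[tuple[int, int]] = []
    for i0, i1 in raw:
        if merged:
            p0, p1 = merged[-1]
            same_dir = (yaw[i1] - yaw[i0]) * (yaw[p1] - yaw[p0]) > 0
            if same_dir and (t[i0] - t[p1]) < merge_gap:
                merged[-1] = (p0, i1)
                continue
        merged.append((i0, i1))

    events = [_event(i0, i1) for i0, i1 in merged if i1 > i0]
    return [e for e in events if abs(e.magnitude) >= min_angle]


def turn_summary(events: list[TurnEvent]) -> TurnSummary:
    """Aggregate per-turn metrics; empty input yields NaN sentinels."""
    if not events:
        return TurnSummary(n_turns=0, mean_turn_time=math.nan,
                           avg_turn_velocity=math.nan, peak_turn_velocity=math.nan)
    return TurnSummary(
        n_turns=len(events),
        mean_turn_time=float(np.mean([e.duration for e in events])),
        avg_turn_velocity=float(np.mean([e.mean_velocity for e in events])),
        peak_turn_velocity=float(np.max([e.peak_velocity for e in events])),
    )


def analyze_turns(
    trace: KinematicsTrace,
    rate_threshold: float = TURN_RATE_THRESHOLD,
    min_angle: float = MIN_TURN_ANGLE,
) -> tuple[list[TurnEvent], TurnSummary]:
    """Heading extraction + segmentation + summary in one call."""
    t, yaw = heading_series(trace)
    events = segment_turns(t, yaw, rate_threshold=rate_threshold, min_angle=min_angle)
    return events, turn_summary(events)
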