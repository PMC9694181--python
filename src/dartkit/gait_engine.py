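"""Spatiotemporal gait metrics from a head-pose trace.

The head of a walking person oscillates vertically once per step; steps are
detected as prominent local maxima of the band-pass-filtered vertical head
position. Gait velocity is horizontal path length over elapsed time (path
length, not net displacement, so closed-loop courses yield sensible speeds).
Cadence and step length follow from the step count, and the three always
satisfy the identity ``velocity = step_length * cadence / 60`` when computed
from the same trace because they share one (distance, steps, duration)
triple.

All algorithms are rate-agnostic: timestamps drive every computation, and
the sampling rate is estimated from the median sample interval only to set
digital-filter coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .kinematics_io import KinematicsTrace

__all__ = [
    "StepEvents",
    "GaitSummary",
    "InsufficientDataError",
    "detect_steps",
    "gait_velocity",
    "cadence",
    "step_length",
    "analyze_gait",
]

#: band containing plausible step frequencies (30-180 steps/min), Hz
STEP_BAND_HZ = (0.5, 3.0)
#: default minimum peak prominence for a step, meters of head bob
MIN_STEP_PROMINENCE_M = 0.005
#: refractory interval between steps (caps cadence at 240 steps/min), s
STEP_REFRACTORY_S = 0.25
#: low-pass cutoff applied to horizontal position before path-length sums, Hz
SPEED_LOWPASS_HZ = 2.0
#: leading/trailing trim to suppress filter edge transients, s
EDGE_TRIM_S = 0.5


class InsufficientDataError(ValueError):
    """The trace is too short for the requested metric."""


@dataclass(frozen=True)
class StepEvents:
    """Detected step instants (one per vertical head-bob maximum)."""

    step_times: np.ndarray  # seconds, strictly increasing

    @property
    def n_steps(self) -> int:
        return int(self.step_times.shape[0])


@dataclass(frozen=True)
class GaitSummary:
    """Per-module spatiotemporal summary; all quantities non-negative.

    ``step_length`` is NaN when no steps were detected (undefined metric),
    in which case cadence is 0.
    """

    gait_velocity: float  # m/s
    cadence: float        # steps/min
    step_length: float    # m
    distance: float       # m
    duration: float       # s
    n_steps: int = 0


def _fs_of(trace: KinematicsTrace) -> float:
    return 1.0 / float(np.median(np.diff(trace.t)))


def _sosfiltfilt(x: np.ndarray, fs: float, cutoff, btype: str, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    wn = np.atleast_1d(np.asarray(cutoff, dtype=float)) / nyq
    if np.any(wn >= 1.0):  # undersampled for this band: leave signal untouched
        if btype == "lowpass":
            return x.copy()
        wn = np.clip(wn, None, 0.99)
    sos = signal.butter(order, wn if wn.size > 1 else wn[0], btype=btype, output="sos")
    padlen = min(3 * (2 * order + 1), x.shape[0] - 1)
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def _analysis_window(trace: KinematicsTrace, trim: float = EDGE_TRIM_S) -> np.ndarray:
    """Boolean mask of samples inside the edge-trimmed analysis window."""
    t0, t1 = trace.t[0] + trim, trace.t[-1] - trim
    if t1 - t0 <= 0:
        raise InsufficientDataError(
            f"trace of {trace.duration:.2f} s is too short for a {trim} s edge trim"
        )
    return (trace.t >= t0) & (trace.t <= t1)


def detect_steps(
    trace: KinematicsTrace,
    min_prominence: float = MIN_STEP_PROMINENCE_M,
    band: tuple[float, float] = STEP_BAND_HZ,
    refractory: float = STEP_REFRACTORY_S,
) -> StepEvents:
    """Detect step instants from vertical head oscillation.

    The vertical position is band-pass filtered (zero-phase Butterworth over
    ``band``), the first/last 0.5 s are trimmed to suppress filter
    transients, and each local maximum with at least ``min_prominence``
    meters of prominence separated by at least ``refractory`` seconds counts
    as one step. Deterministic for fixed input and configuration.
    """
    if trace.duration < 2.0:
        raise InsufficientDataError(f"step detection needs >= 2 s of data, got {trace.duration:.2f} s")
    fs = _fs_of(trace)
    y = _sosfiltfilt(trace.pos[:, 1], fs, band, "bandpass")
    mask = _analysis_window(trace)
    yw, tw = y[mask], trace.t[mask]
    distance = max(1, int(round(refractory * fs)))
    peaks, _ = signal.find_peaks(yw, prominence=min_prominence, distance=distance)
    return StepEvents(step_times=tw[peaks])


def _horizontal_path(trace: KinematicsTrace, mask: Optional[np.ndarray] = None) -> float:
    """Smoothed horizontal (x, z) path length in meters over masked samples."""
    fs = _fs_of(trace)
    xz = np.column_stack([
        _sosfiltfilt(trace.pos[:, 0], fs, SPEED_LOWPASS_HZ, "lowpass"),
        _sosfiltfilt(trace.pos[:, 2], fs, SPEED_LOWPASS_HZ, "lowpass"),
    ])
    if mask is not None:
        xz = xz[mask]
    if xz.shape[0] < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(xz, axis=0), axis=1)))


def _excluded_mask(t: np.ndarray, exclude: Optional[Sequence[tuple[float, float]]]) -> np.ndarray:
    keep = np.ones_like(t, dtype=bool)
    for a, b in exclude or ():
        keep &= ~((t >= a) & (t <= b))
    return keep


def gait_velocity(
    trace: KinematicsTrace,
    exclude: Optional[Sequence[tuple[float, float]]] = None,
) -> float:
    """Average walking speed: horizontal path length / elapsed time, m/s.

    ``exclude`` is a list of (t_on, t_off) intervals (e.g. turns or freezing
    episodes) whose samples contribute neither distance nor time.
    """
    if trace.duration <= 0:
        raise InsufficientDataError("zero-duration trace")
    keep = _excluded_mask(trace.t, exclude)
    if keep.sum() < 2:
        raise InsufficientDataError("exclusion intervals removed the entire trace")
    dist = _horizontal_path(trace, keep)
    dt = np.diff(trace.t)
    elapsed = float(np.sum(dt[keep[1:] & keep[:-1]]))
    if elapsed <= 0:
        raise InsufficientDataError("no time remains after exclusions")
    return dist / elapsed


def cadence(steps: StepEvents, duration: float) -> float:
    """Steps per minute: ``60 * n_steps / duration``."""
    if duration <= 0:
        raise InsufficientDataError(f"duration must be > 0, got {duration}")
    return 60.0 * steps.n_steps / duration


def step_length(distance: float, n_steps: int) -> float:
    """Meters per step; NaN (undefined-metric sentinel) when no steps."""
    if n_steps < 1:
        return math.nan
    return distance / n_steps


def analyze_gait(
    trace: KinematicsTrace,
    exclude: Optional[Sequence[tuple[float, float]]] = None,
    min_prominence: float = MIN_STEP_PROMINENCE_M,
    band: tuple[float, float] = STEP_BAND_HZ,
) -> GaitSummary:
    """Full spatiotemporal summary over one edge-trimmed analysis window.

    Distance, duration and step count are all measured over the same window
    (and outside ``exclude`` intervals), so the reported velocity, cadence
    and step length satisfy velocity = step_length * cadence / 60 exactly.
    """
    steps = detect_steps(trace, min_prominence=min_prominence, band=band)
    window = _analysis_window(trace)
    keep = window & _excluded_mask(trace.t, exclude)
    if keep.sum() < 2:
        raise InsufficientDataError("analysis window is empty after exclusions")
    dist = _horizontal_path(trace, keep)
    dt = np.diff(trace.t)
    duration = float(np.sum(dt[keep[1:] & keep[:-1]]))
    if duration <= 0:
        raise InsufficientDataError("no analyzable time in window")
    kept_steps = steps
    if exclude:
        m = _excluded_mask(steps.step_times, exclude)
        kept_steps = StepEvents(step_times=steps.step_times[m])
    n = kept_steps.n_steps
    return GaitSummary(
        gait_velocity=dist / duration,
        cadence=60.0 * n / duration,
        step_length=step_length(dist, n),
        distance=dist,
        duration=duration,
        n_steps=n,
    )
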