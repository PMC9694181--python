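"""Synthetic head-trajectory generator with ground truth.

Stands in for head-mounted AR recordings so every analysis component can be
verified without hardware. The model is deliberately phenomenological: the
head advances along a commanded path at a commanded speed, oscillates
vertically once per step (head bob) and laterally once per stride (sway),
and turns follow trapezoidal angular-velocity profiles that reach a
commanded peak. Freezing-of-gait (FOG) episodes freeze horizontal
progression and suppress the bob while retaining sensor jitter. Gaussian
positional noise emulates tracker jitter. Everything is deterministic for a
fixed seed, and a GroundTruth record stores every commanded quantity so
recovery error can be measured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .kinematics_io import KinematicsTrace

__all__ = [
    "WalkParams",
    "Straight",
    "Turn",
    "Stop",
    "CoursePath",
    "GroundTruth",
    "simulate_walk",
    "circuit_duration",
    "make_obstacle_course",
    "make_figure_of_eight",
    "simulate_cohort",
    "SINGLE_TASK_POINT",
    "DUAL_TASK_POINT",
]

#: cohort operating points (group mean (SD) per metric) used by presets
SINGLE_TASK_POINT = {
    "gait_velocity": (1.06, 0.17),       # m/s
    "cadence": (96.9, 9.6),              # steps/min
    "step_length": (0.63, 0.10),         # m
    "peak_turn_velocity": (187.9, 52.8), # deg/s
}
DUAL_TASK_POINT = {
    "gait_velocity": (0.82, 0.19),
    "cadence": (88.2, 14.1),
    "step_length": (0.53, 0.10),
    "peak_turn_velocity": (146.9, 61.3),
}

_TURN_RAMP_S = 0.2  # angular acceleration/deceleration ramp of a commanded turn


@dataclass
class WalkParams:
    """Commanded gait parameters.

    Exactly two of ``speed`` (m/s), ``cadence`` (steps/min) and
    ``step_length`` (m) must be given; the third is implied through
    ``speed = step_length * cadence / 60`` and must land in (0.1, 1.5) m.
    """

    speed: Optional[float] = None
    cadence: Optional[float] = None
    step_length: Optional[float] = None
    duration: float = 60.0
    sample_rate: float = 60.0
    bob_amplitude: float = 0.02    # m, vertical oscillation per step
    sway_amplitude: float = 0.02   # m, lateral oscillation per stride
    noise_sd: float = 0.003        # m, per-axis positional jitter
    yaw_noise_sd: float = 0.1      # deg, orientation jitter
    head_height: float = 1.6       # m
    seed: int = 0

    def __post_init__(self) -> None:
        given = [v is not None for v in (self.speed, self.cadence, self.step_length)]
        if sum(given) != 2:
            raise ValueError("specify exactly two of speed, cadence, step_length")
        if self.speed is None:
            self.speed = self.step_length * self.cadence / 60.0
        elif self.cadence is None:
            self.cadence = 60.0 * self.speed / self.step_length
        else:
            self.step_length = 60.0 * self.speed / self.cadence
        if not (self.speed > 0 and self.cadence > 0 and self.duration > 0):
            raise ValueError("speed, cadence and duration must all be > 0")
        if not (0.1 < self.step_length < 1.5):
            raise ValueError(f"implied step length {self.step_length:.3f} m outside (0.1, 1.5)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


@dataclass(frozen=True)
class Straight:
    """Walk straight ahead for ``length`` meters."""
    length: float


@dataclass(frozen=True)
class Turn:
    """Turn in place-of-path by ``angle`` degrees (+ = left) while walking.

    Angular velocity follows a trapezoid that ramps to ``peak_velocity``
    (deg/s) over 0.2 s, holds, and ramps down; small angles degrade to a
    triangle that still touches the commanded peak.
    """
    angle: float
    peak_velocity: float

    def __post_init__(self) -> None:
        if self.peak_velocity <= 0:
            raise ValueError("commanded peak angular velocity must be > 0")
        if self.angle == 0:
            raise ValueError("turn angle must be nonzero")


@dataclass(frozen=True)
class Stop:
    """Stand still for ``duration`` seconds (scripted freezing episode)."""
    duration: float


Segment = Union[Straight, Turn, Stop]


@dataclass
class CoursePath:
    """A walking course as an ordered list of segments.

    ``fog_episodes`` are (t_start, duration) wall-clock intervals during
    which horizontal progression is frozen regardless of the segment the
    walker is in, emulating unscripted freezing of gait.
    """

    segments: list[Segment]
    loop: bool = False
    fog_episodes: list[tuple[float, float]] = field(default_factory=list)

    @classmethod
    def from_waypoints(
        cls,
        waypoints: Sequence[tuple[float, float]],
        peak_turn_velocity: float = 120.0,
        loop: bool = False,
    ) -> "CoursePath":
        """Build a course from (x, z) waypoints; corners become turns."""
        pts = [np.asarray(p, dtype=float) for p in waypoints]
        if len(pts) < 2:
            raise ValueError("need at least 2 waypoints")
        for a, b in zip(pts, pts[1:]):
            if np.allclose(a, b):
                raise ValueError("consecutive waypoints must be distinct")
        headings = []
        legs = []
        closed = pts + [pts[0]] if loop else pts
        for a, b in zip(closed, closed[1:]):
            d = b - a
            legs.append(float(np.hypot(*d)))
            headings.append(math.degrees(math.atan2(d[0], d[1])))  # yaw: atan2(x, z)
        segs: list[Segment] = []
        for i, length in enumerate(legs):
            segs.append(Straight(length))
            nxt = (i + 1) % len(headings)
            if not loop and nxt == 0:
                break
            dh = (headings[nxt] - headings[i] + 180.0) % 360.0 - 180.0
            if abs(dh) > 1e-9:
                segs.append(Turn(dh, peak_turn_velocity))
        return cls(segments=segs, loop=loop)

    def waypoints(self) -> list[tuple[float, float]]:
        """Idealized corner points of the course (turns taken as pivots)."""
        x, z, yaw = 0.0, 0.0, 0.0
        pts = [(x, z)]
        for seg in self.segments:
            if isinstance(seg, Straight):
                x += seg.length * math.sin(math.radians(yaw))
                z += seg.length * math.cos(math.radians(yaw))
                pts.append((x, z))
            elif isinstance(seg, Turn):
                yaw += seg.angle
        return pts


@dataclass
class GroundTruth:
    """Everything the generator commanded, for recovery-error measurement."""

    speed: float
    cadence: float
    step_length: float
    step_times: np.ndarray
    turns: list[dict]                      # {t_on, t_off, angle, peak_velocity}
    fog_intervals: list[tuple[float, float]]
    duration: float


def _turn_profile(angle: float, peak: float, ramp: float = _TURN_RAMP_S) -> tuple[float, float]:
    """(total duration, plateau duration) of the trapezoidal turn profile."""
    base = abs(angle) / peak
    if base >= ramp:
        return base + ramp, base - ramp
    return 2.0 * base, 0.0  # triangular, still touches the commanded peak


def _turn_rate_at(tau: float, angle: float, peak: float, ramp: float = _TURN_RAMP_S) -> float:
    total, plateau = _turn_profile(angle, peak, ramp)
    r = min(ramp, total / 2.0)
    if tau < 0 or tau > total:
        return 0.0
    if tau < r:
        mag = peak * tau / r
    elif tau > total - r:
        mag = peak * (total - tau) / r
    else:
        mag = peak
    return math.copysign(mag, angle)


def simulate_walk(
    params: WalkParams,
    path: Optional[CoursePath] = None,
) -> tuple[KinematicsTrace, GroundTruth]:
    """Synthesize a head-pose trace along ``path`` (straight line if None).

    The head position is the path progression at the commanded speed plus a
    vertical sinusoid at step frequency (amplitude ``bob_amplitude``), a
    lateral sinusoid at half step frequency (stride sway), the head height
    offset, and per-axis Gaussian noise. Orientation (quaternion, Euler,
    gaze) follows the path tangent with small yaw jitter. During commanded
    stops and FOG episodes horizontal progression and bob freeze, while
    noise persists. Step times, turn windows and commanded values are
    returned as ground truth.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate
    dt = 1.0 / fs
    n = int(round(params.duration * fs)) + 1
    t = np.arange(n) * dt
    f_step = params.cadence / 60.0

    segments = path.segments if path is not None else [Straight(params.speed * params.duration * 2)]
    loop = path.loop if path is not None else False
    fog = list(path.fog_episodes) if path is not None else []

    def in_fog(tk: float) -> bool:
        return any(a <= tk < a + d for a, d in fog)

    x = np.zeros(n)
    z = np.zeros(n)
    yaw = np.zeros(n)
    walking = np.zeros(n, dtype=bool)
    bob_phase = np.zeros(n)

    seg_idx, seg_pos = 0, 0.0  # seg_pos: meters into a Straight / seconds into a Turn or Stop
    cx = cz = cyaw = 0.0
    phase = 0.0
    turn_windows: list[dict] = []
    open_turn: Optional[dict] = None

    for k in range(n):
        x[k], z[k], yaw[k], bob_phase[k] = cx, cz, cyaw, phase
        v = w = 0.0
        walk = False
        frozen = in_fog(t[k])
        if not frozen and seg_idx < len(segments):
            seg = segments[seg_idx]
            if isinstance(seg, Straight):
                v, walk = params.speed, True
                seg_pos += v * dt
                advance = seg_pos >= seg.length
            elif isinstance(seg, Turn):
                if open_turn is None:
                    open_turn = {"t_on": t[k], "angle": seg.angle, "peak_velocity": seg.peak_velocity}
                w = _turn_rate_at(seg_pos, seg.angle, seg.peak_velocity)
                v, walk = params.speed, True
                seg_pos += dt
                total, _ = _turn_profile(seg.angle, seg.peak_velocity)
                advance = seg_pos >= total
                if advance:
                    open_turn["t_off"] = t[k]
                    turn_windows.append(open_turn)
                    open_turn = None
            else:  # Stop
                seg_pos += dt
                advance = seg_pos >= seg.duration
            if advance:
                seg_idx += 1
                seg_pos = 0.0
                if seg_idx >= len(segments) and loop:
                    seg_idx = 0
        walking[k] = walk
        cyaw += w * dt
        hd = math.radians(cyaw)
        cx += v * math.sin(hd) * dt
        cz += v * math.cos(hd) * dt
        if walk:
            phase += 2.0 * math.pi * f_step * dt

    if open_turn is not None:  # trace ended mid-turn
        open_turn["t_off"] = t[-1]
        turn_windows.append(open_turn)

    # ground-truth step times: bob maxima, i.e. phase crossings of pi/2 + 2*pi*m
    shifted = bob_phase - math.pi / 2.0
    crossing = np.floor(shifted / (2 * math.pi))
    step_mask = np.diff(crossing) > 0
    step_times = t[1:][step_mask]

    yaw_rad = np.radians(yaw)
    heading = np.column_stack([np.sin(yaw_rad), np.zeros(n), np.cos(yaw_rad)])
    left = np.column_stack([np.cos(yaw_rad), np.zeros(n), -np.sin(yaw_rad)])

    bob = params.bob_amplitude * np.sin(bob_phase)
    sway = params.sway_amplitude * np.sin(bob_phase / 2.0)
    pos = np.column_stack([x, np.full(n, params.head_height), z])
    pos += left * sway[:, None]
    pos[:, 1] += bob
    pos += rng.normal(0.0, params.noise_sd, size=(n, 3))

    yaw_noisy = yaw + rng.normal(0.0, params.yaw_noise_sd, size=n)
    yaw_wrapped = (yaw_noisy + 180.0) % 360.0 - 180.0
    half = np.radians(yaw_noisy) / 2.0
    quat = np.column_stack([np.cos(half), np.zeros(n), np.sin(half), np.zeros(n)])
    euler = np.column_stack([np.zeros(n), yaw_wrapped, np.zeros(n)])
    ynr = np.radians(yaw_noisy)
    gaze = np.column_stack([np.sin(ynr), np.zeros(n), np.cos(ynr)])

    trace = KinematicsTrace(t=t, pos=pos, euler=euler, quat=quat, gaze=gaze,
                            nominal_rate=fs)
    truth = GroundTruth(
        speed=params.speed,
        cadence=params.cadence,
        step_length=params.step_length,
        step_times=step_times,
        turns=turn_windows,
        fog_intervals=list(fog),
        duration=params.duration,
    )
    return trace, truth


def circuit_duration(path: CoursePath, speed: float) -> float:
    """Time to traverse the segment list once at ``speed`` (seconds)."""
    if speed <= 0:
        raise ValueError("speed must be > 0")
    total = 0.0
    for seg in path.segments:
        if isinstance(seg, Straight):
            total += seg.length / speed
        elif isinstance(seg, Turn):
            total += _turn_profile(seg.angle, seg.peak_velocity)[0]
        else:
            total += seg.duration
    return total


def _sidestep(direction: float, clearance: float = 1.0, angle: float = 30.0,
              peak: float = 60.0) -> list[Segment]:
    """Lateral deviation around a pillar: four sub-threshold heading changes."""
    a = math.copysign(angle, direction)
    return [
        Turn(a, peak), Straight(clearance),
        Turn(-a, peak), Straight(clearance),
        Turn(-a, peak), Straight(clearance),
        Turn(a, peak),
    ]


def make_obstacle_course(
    n_pillars: int = 3,
    doorway: bool = True,
    lap_length: float = 20.0,
    seed: int = 0,
    end_turn_peak: float = 150.0,
    fog_episodes: Optional[list[tuple[float, float]]] = None,
) -> CoursePath:
    """Closed-loop obstacle course: two straights joined by 180° end turns.

    Pillars are placed on the straights and require sidestepping (heading
    deviations kept below the turn-detection minimum angle); a doorway is a
    narrowed passage marker near the end of the return straight. Deviation
    sides are drawn deterministically from ``seed``.
    """
    if lap_length <= 2.0:
        raise ValueError("lap_length must exceed 2 m")
    if n_pillars < 0:
        raise ValueError("n_pillars must be >= 0")
    rng = np.random.default_rng(seed)
    straight = lap_length / 2.0
    out_pillars = (n_pillars + 1) // 2
    back_pillars = n_pillars - out_pillars

    def leg(n_p: int) -> list[Segment]:
        if n_p == 0:
            return [Straight(straight)]
        gap = straight / (n_p + 1)
        segs: list[Segment] = []
        for _ in range(n_p):
            segs.append(Straight(gap))
            segs.extend(_sidestep(1.0 if rng.random() < 0.5 else -1.0))
        segs.append(Straight(gap))
        return segs

    segments: list[Segment] = []
    segments.extend(leg(out_pillars))
    segments.append(Turn(180.0, end_turn_peak))
    segments.extend(leg(back_pillars))
    if doorway:
        # doorway: a short constrained passage before the lap closes;
        # kinematically a plain straight, it is where FOG episodes cluster
        segments.append(Straight(1.0))
    segments.append(Turn(180.0, end_turn_peak))
    return CoursePath(segments=segments, loop=True,
                      fog_episodes=list(fog_episodes or []))


def make_figure_of_eight(
    straight_length: float = 4.0,
    peak_turn_velocity: float = 150.0,
) -> CoursePath:
    """Looping figure-of-eight: alternating pairs of left and right 180° turns.

    One circuit contains two left and two right half-turns (720° of total
    rotation magnitude), emulating the repetitive left- and right-hand
    turning course.
    """
    s = Straight(straight_length)
    return CoursePath(
        segments=[
            s, Turn(180.0, peak_turn_velocity),
            s, Turn(180.0, peak_turn_velocity),
            s, Turn(-180.0, peak_turn_velocity),
            s, Turn(-180.0, peak_turn_velocity),
        ],
        loop=True,
    )


def simulate_cohort(
    n: int,
    single_point: Optional[dict] = None,
    dual_point: Optional[dict] = None,
    correlation: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw paired per-subject gait summaries for a two-condition cohort.

    For each metric the (single, dual) pair is drawn from a bivariate normal
    with the given condition means/SDs and within-subject correlation.
    Returns a DataFrame with one row per subject and columns
    ``<metric>_single`` / ``<metric>_dual``.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    if not (-1.0 <= correlation <= 1.0):
        raise ValueError(f"correlation must lie in [-1, 1], got {correlation}")
    single_point = single_point or SINGLE_TASK_POINT
    dual_point = dual_point or DUAL_TASK_POINT
    if set(single_point) != set(dual_point):
        raise ValueError("single and dual operating points must share metrics")
    rng = np.random.default_rng(seed)
    out = {}
    for metric in single_point:
        m1, s1 = single_point[metric]
        m2, s2 = dual_point[metric]
        cov = np.array([
            [s1 * s1, correlation * s1 * s2],
            [correlation * s1 * s2, s2 * s2],
        ])
        draws = rng.multivariate_normal([m1, m2], cov, size=n)  # svd handles r = ±1
        out[f"{metric}_single"] = draws[:, 0]
        out[f"{metric}_dual"] = draws[:, 1]
    return pd.DataFrame(out)
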