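"""Synchronous session loop: instantaneous speed, 5-second status messages,
pace-setter feedback, and the session control state machine.

The original platform streams a JSON status message from the headset to the
supervising clinician every five seconds, carrying the module in progress,
elapsed/remaining time and the current walking speed, and the clinician can
pause, resume, skip or terminate modules. Here that loop is emulated
in-process: a replay driver walks a recorded (or synthetic) trace through a
session plan and yields schema-valid status messages in simulated time.
"""

from __future__ import annotations

import enum
import logging
from typing import Iterator, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .gait_engine import _horizontal_path
from .kinematics_io import KinematicsTrace
from .session_model import ModulePlan

logger = logging.getLogger(__name__)

__all__ = [
    "STATUS_PERIOD_S",
    "StatusMessage",
    "SessionStatus",
    "SessionState",
    "IllegalTransition",
    "instantaneous_speed",
    "emit_status",
    "pace_setter_feedback",
    "PaceColor",
    "STOP_SPEED_EPS",
]

#: status-message cadence, seconds
STATUS_PERIOD_S = 5.0
#: below this speed the walker counts as stopped, m/s
STOP_SPEED_EPS = 0.1


class StatusMessage(BaseModel):
    """One 5-second status update from headset to clinician dashboard."""

    module_id: str
    motor_task: str
    cognitive_task: Optional[str] = None
    elapsed_s: float = Field(ge=0)
    time_remaining_s: float = Field(ge=0)
    current_speed_mps: float = Field(ge=0)
    timestamp_s: float


class SessionStatus(str, enum.Enum):
    IDLE = "idle"
    RUNNING = "running"
    PAUSED = "paused"
    TERMINATED = "terminated"
    COMPLETED = "completed"


class IllegalTransition(RuntimeError):
    pass


_LEGAL = {
    SessionStatus.IDLE: {SessionStatus.RUNNING},
    SessionStatus.RUNNING: {SessionStatus.PAUSED, SessionStatus.TERMINATED, SessionStatus.COMPLETED},
    SessionStatus.PAUSED: {SessionStatus.RUNNING, SessionStatus.TERMINATED},
    SessionStatus.TERMINATED: set(),
    SessionStatus.COMPLETED: set(),
}


class SessionState:
    """Control state machine for a running session.

    Only the documented transitions are legal (start, pause/resume,
    terminate, complete); ``skip`` advances the module index while running
    or paused.
    """

    def __init__(self, n_modules: int) -> None:
        if n_modules < 1:
            raise ValueError("a session needs at least one module")
        self.status = SessionStatus.IDLE
        self.module_index = 0
        self.n_modules = n_modules

    def _goto(self, new: SessionStatus) -> None:
        if new not in _LEGAL[self.status]:
            raise IllegalTransition(f"cannot go {self.status.value} -> {new.value}")
        self.status = new

    def start(self) -> None:
        self._goto(SessionStatus.RUNNING)

    def pause(self) -> None:
        self._goto(SessionStatus.PAUSED)

    def resume(self) -> None:
        if self.status is not SessionStatus.PAUSED:
            raise IllegalTransition(f"cannot resume from {self.status.value}")
        self.status = SessionStatus.RUNNING

    def terminate(self) -> None:
        self._goto(SessionStatus.TERMINATED)

    def complete(self) -> None:
        self._goto(SessionStatus.COMPLETED)

    def skip(self) -> None:
        if self.status not in (SessionStatus.RUNNING, SessionStatus.PAUSED):
            raise IllegalTransition(f"cannot skip while {self.status.value}")
        if self.module_index + 1 >= self.n_modules:
            self.complete()
        else:
            self.module_index += 1


def instantaneous_speed(
    trace: KinematicsTrace,
    t_end: float,
    window: float = STATUS_PERIOD_S,
) -> float:
    """Current walking speed: horizontal path length over the trailing window.

    Returns 0 (with a logged warning) when the window holds fewer than two
    samples.
    """
    mask = (trace.t > t_end - window) & (trace.t <= t_end)
    if mask.sum() < 2:
        logger.warning("instantaneous_speed: empty window ending at t=%.2f s", t_end)
        return 0.0
    tw = trace.t[mask]
    span = float(tw[-1] - tw[0])
    if span <= 0:
        return 0.0
    return _horizontal_path(trace, mask) / span


def emit_status(
    module: ModulePlan,
    trace: KinematicsTrace,
    pauses: Optional[Sequence[tuple[float, float]]] = None,
    period: float = STATUS_PERIOD_S,
) -> Iterator[StatusMessage]:
    """Replay one module and yield status messages every ``period`` seconds
    of *active* (unpaused) time.

    ``pauses`` are (t_pause, t_resume) wall-clock intervals; no messages are
    emitted inside a pause and elapsed time excludes paused time. The stream
    ends when active time reaches the module duration or the trace runs out.
    """
    pauses = sorted(pauses or [])
    t0 = float(trace.t[0])
    t_end_trace = float(trace.t[-1])

    def active_time(t: float) -> float:
        paused = sum(max(0.0, min(t, b) - min(t, a)) for a, b in pauses)
        return (t - t0) - paused

    def in_pause(t: float) -> bool:
        return any(a <= t < b for a, b in pauses)

    k = 1
    t = t0
    dt = float(np.median(np.diff(trace.t)))
    while t <= t_end_trace + dt / 2:
        if not in_pause(t) and active_time(t) >= k * period - dt / 2:
            elapsed = k * period
            if elapsed > module.duration_s:
                break
            yield StatusMessage(
                module_id=f"module-{module.order_index}",
                motor_task=module.motor.id.value,
                cognitive_task=module.cognitive.id if module.cognitive else None,
                elapsed_s=elapsed,
                time_remaining_s=max(0.0, module.duration_s - elapsed),
                current_speed_mps=max(0.0, instantaneous_speed(trace, t, window=period)),
                timestamp_s=t,
            )
            if elapsed >= module.duration_s:
                break
            k += 1
        t += dt


class PaceColor(str, enum.Enum):
    RED = "red"
    ORANGE = "orange"
    GREEN = "green"


def pace_setter_feedback(
    current_speed: float,
    target_speed: float,
    stop_eps: float = STOP_SPEED_EPS,
) -> PaceColor:
    """Pace-setter icon color: red if stopped, orange below target, green at
    or above target."""
    if target_speed <= 0:
        raise ValueError(f"target_speed must be > 0, got {target_speed}")
    if current_speed < stop_eps:
        return PaceColor.RED
    if current_speed < target_speed:
        return PaceColor.ORANGE
    return PaceColor.GREEN
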