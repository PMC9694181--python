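"""Readers and writers for recorded session data.

Three on-disk artifacts are supported:

* the head-pose CSV — one row per sample: timestamp, head position (m),
  rotation as Euler angles (deg) and as a unit quaternion, and the gaze
  direction unit vector;
* the cognitive-result JSON — the delivered stimuli and scored responses;
* status-message JSON (schema owned by :mod:`dartkit.realtime_feedback`).

Coordinate convention used throughout the package: meters, Y-up,
right-handed; x is lateral (positive left), z is forward at zero yaw; yaw is
rotation about +Y, positive for a left turn. Values are quantized on write
(time and position to 1e-4, angles/quaternions/gaze to 1e-9) so a
write -> read cycle is the identity at that precision and a second cycle is
bitwise identity.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from typing import IO, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel

logger = logging.getLogger(__name__)

__all__ = [
    "POSE_CSV_COLUMNS",
    "PoseSample",
    "KinematicsTrace",
    "CognitiveResult",
    "TraceSchemaError",
    "TraceValidationError",
    "read_trace",
    "write_trace",
    "read_cognitive_results",
    "write_cognitive_results",
]

POSE_CSV_COLUMNS = (
    "t",
    "pos_x", "pos_y", "pos_z",
    "eul_x", "eul_y", "eul_z",
    "quat_w", "quat_x", "quat_y", "quat_z",
    "gaze_x", "gaze_y", "gaze_z",
)

_UNIT_NORM_TOL = 1e-6


class TraceSchemaError(ValueError):
    """The CSV header or structure does not match the documented schema."""


class TraceValidationError(ValueError):
    """Sample values violate a trace invariant (norms, monotone time)."""


@dataclass(frozen=True)
class PoseSample:
    """A single head-pose sample (a row view into a trace)."""

    t: float
    pos: np.ndarray     # (3,) meters, [x lateral, y up, z forward]
    euler: np.ndarray   # (3,) degrees
    quat: np.ndarray    # (4,) unit quaternion (w, x, y, z)
    gaze: np.ndarray    # (3,) unit gaze direction


@dataclass
class KinematicsTrace:
    """A timestamped head-pose stream stored as dense arrays.

    Attributes
    ----------
    t : (n,) seconds, strictly increasing
    pos : (n, 3) meters
    euler : (n, 3) degrees
    quat : (n, 4) unit quaternions, scalar-first
    gaze : (n, 3) unit vectors
    module_id : identifier of the session module this trace belongs to
    nominal_rate : nominal sampling rate in Hz (informational; all
        computations use the timestamps)
    """

    t: np.ndarray
    pos: np.ndarray
    euler: np.ndarray
    quat: np.ndarray
    gaze: np.ndarray
    module_id: Optional[str] = None
    nominal_rate: Optional[float] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.euler = np.asarray(self.euler, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        self.gaze = np.asarray(self.gaze, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.t.shape[0]
        if n < 2:
            raise TraceValidationError(f"a trace needs at least 2 samples, got {n}")
        for name, arr, width in (
            ("pos", self.pos, 3), ("euler", self.euler, 3),
            ("quat", self.quat, 4), ("gaze", self.gaze, 3),
        ):
            if arr.shape != (n, width):
                raise TraceValidationError(f"{name} must have shape ({n}, {width}), got {arr.shape}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise TraceValidationError(f"timestamps must be strictly increasing (violation at row {i + 1})")
        qn = np.linalg.norm(self.quat, axis=1)
        bad = np.abs(qn - 1.0) > _UNIT_NORM_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise TraceValidationError(f"quaternion norm {qn[i]:.6f} at row {i} outside 1 ± {_UNIT_NORM_TOL}")
        gn = np.linalg.norm(self.gaze, axis=1)
        bad = np.abs(gn - 1.0) > _UNIT_NORM_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise TraceValidationError(f"gaze norm {gn[i]:.6f} at row {i} outside 1 ± {_UNIT_NORM_TOL}")

    def __len__(self) -> int:
        return self.t.shape[0]

    def __getitem__(self, i: int) -> PoseSample:
        return PoseSample(
            t=float(self.t[i]), pos=self.pos[i], euler=self.euler[i],
            quat=self.quat[i], gaze=self.gaze[i],
        )

    @property
    def samples(self) -> Iterator[PoseSample]:
        return (self[i] for i in range(len(self)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


def read_trace(source: Union[str, IO[str], IO[bytes]]) -> KinematicsTrace:
    """Read a pose CSV into a :class:`KinematicsTrace`.

    Strict on schema (exact documented column set); rows containing NaN are
    dropped with a logged count; invariant violations raise
    :class:`TraceValidationError` naming the offending row.
    """
    try:
        df = pd.read_csv(source)
    except pd.errors.EmptyDataError:
        raise TraceSchemaError("empty pose CSV: no header row") from None
    missing = [c for c in POSE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TraceSchemaError(f"pose CSV is missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in POSE_CSV_COLUMNS]
    if extra:
        raise TraceSchemaError(f"pose CSV has unexpected column(s): {', '.join(extra)}")
    if df.shape[0] == 0:
        raise TraceSchemaError("pose CSV contains a header but no samples")
    n_raw = df.shape[0]
    df = df.dropna()
    if (dropped := n_raw - df.shape[0]) > 0:
        logger.warning("dropped %d row(s) containing NaN from pose CSV", dropped)
    df = df[list(POSE_CSV_COLUMNS)]
    return KinematicsTrace(
        t=df["t"].to_numpy(),
        pos=df[["pos_x", "pos_y", "pos_z"]].to_numpy(),
        euler=df[["eul_x", "eul_y", "eul_z"]].to_numpy(),
        quat=df[["quat_w", "quat_x", "quat_y", "quat_z"]].to_numpy(),
        gaze=df[["gaze_x", "gaze_y", "gaze_z"]].to_numpy(),
    )


def write_trace(trace: KinematicsTrace, dest: Union[str, IO[str], None] = None) -> Optional[str]:
    """Write a trace as CSV; returns the CSV text when ``dest`` is None.

    Time and position are written with 4 decimals, angles / quaternions /
    gaze with 9, so that a read-back reproduces the quantized values exactly
    and quaternion norms stay within the 1e-6 unit tolerance.
    """
    if len(trace) < 2:
        raise TraceValidationError("refusing to write a trace with fewer than 2 samples")
    cols = {
        "t": trace.t,
        "pos_x": trace.pos[:, 0], "pos_y": trace.pos[:, 1], "pos_z": trace.pos[:, 2],
        "eul_x": trace.euler[:, 0], "eul_y": trace.euler[:, 1], "eul_z": trace.euler[:, 2],
        "quat_w": trace.quat[:, 0], "quat_x": trace.quat[:, 1],
        "quat_y": trace.quat[:, 2], "quat_z": trace.quat[:, 3],
        "gaze_x": trace.gaze[:, 0], "gaze_y": trace.gaze[:, 1], "gaze_z": trace.gaze[:, 2],
    }
    buf = io.StringIO()
    buf.write(",".join(POSE_CSV_COLUMNS) + "\n")
    coarse = {"t", "pos_x", "pos_y", "pos_z"}
    fmt = ["%.4f" if c in coarse else "%.9f" for c in POSE_CSV_COLUMNS]
    data = np.column_stack([cols[c] for c in POSE_CSV_COLUMNS])
    for row in data:
        buf.write(",".join(f % v for f, v in zip(fmt, row)) + "\n")
    text = buf.getvalue()
    if dest is None:
        return text
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        dest.write(text)
    return None


class CognitiveResult(BaseModel):
    """One delivered cognitive stimulus and the scored response.

    ``scoreable`` is false exactly when there is no correct answer (an
    open-ended prompt); such items are excluded from percent-correct.
    """

    item_id: str
    stimulus: dict
    correct_answer: Optional[str] = None
    given_response: Optional[str] = None
    response_time_s: Optional[float] = None
    scoreable: bool = True
    correct: Optional[bool] = None

    def model_post_init(self, __context) -> None:
        if self.correct_answer is None:
            object.__setattr__(self, "scoreable", False)


def write_cognitive_results(results: Sequence[CognitiveResult], dest: Union[str, IO[str], None] = None) -> Optional[str]:
    """Serialize cognitive results to JSON (a list under key ``results``)."""
    payload = {"schema": "dartkit.cognitive_results.v1",
               "results": [r.model_dump() for r in results]}
    text = json.dumps(payload, indent=1)
    if dest is None:
        return text
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        dest.write(text)
    return None


def read_cognitive_results(source: Union[str, IO[str]]) -> list[CognitiveResult]:
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    else:
        payload = json.load(source)
    if not isinstance(payload, dict) or "results" not in payload:
        raise TraceSchemaError("cognitive-result JSON must contain a 'results' list")
    return [CognitiveResult.model_validate(r) for r in payload["results"]]
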