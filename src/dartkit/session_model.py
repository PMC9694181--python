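"""Typed catalog of motor and cognitive training tasks and the session plan model.

A treatment session is an ordered list of modules; each module pairs one of 14
motor tasks with (optionally) one of 17 cognitive tasks for a fixed duration.
A designated single-task "warm-up" module supplies the reference values against
which every dual-task module is percent-scaled for clinician color coding.
"""

from __future__ import annotations

import enum
from typing import Any, Optional

from pydantic import BaseModel, Field, field_validator

__all__ = [
    "MotorTaskId",
    "DeficitTarget",
    "CognitiveDomain",
    "MotorTask",
    "CognitiveTask",
    "ModulePlan",
    "SessionPlan",
    "ValidationFinding",
    "MOTOR_CATALOG",
    "COGNITIVE_CATALOG",
    "validate_session",
    "pace_setter_target",
]


class MotorTaskId(str, enum.Enum):
    FORWARD_WALKING = "forward_walking"
    BACKWARD_WALKING = "backward_walking"
    LATERAL_WALKING = "lateral_walking"
    PACE_SETTER = "pace_setter"
    MARCHING = "marching"
    HEEL_KICKING = "heel_kicking"
    ARM_SWINGS = "arm_swings"
    TARGETED_ARM_SWINGS = "targeted_arm_swings"
    FOOTPRINT_TARGETS = "footprint_targets"
    GAIT_INITIATION = "gait_initiation"
    FIGURE_OF_EIGHT = "figure_of_eight"
    OBSTACLE_COURSE = "obstacle_course"
    TARGETED_MOVEMENTS = "targeted_movements"
    FLYING_TARGETS = "flying_targets"


class DeficitTarget(str, enum.Enum):
    """Parkinsonian gait deficit a motor task is designed to address."""

    GAIT_AUTOMATICITY = "decreased_gait_automaticity"
    GAIT_VELOCITY = "decreased_gait_velocity"
    MOVEMENT_AMPLITUDE = "decreased_amplitude_of_movement"
    STEP_LENGTH = "decreased_step_length"
    TURNING_INITIATION_FOG = "impaired_turning_gait_initiation_fog"
    OBJECT_NAVIGATION = "impaired_object_navigation"
    POSTURAL_CONTROL = "postural_control_disturbances"


class CognitiveDomain(str, enum.Enum):
    ATTENTION = "attention"
    MEMORY = "memory"
    LANGUAGE = "language"
    EXECUTIVE_FUNCTION = "executive_function"


_DEFICIT_BY_TASK: dict[MotorTaskId, DeficitTarget] = {
    MotorTaskId.FORWARD_WALKING: DeficitTarget.GAIT_AUTOMATICITY,
    MotorTaskId.BACKWARD_WALKING: DeficitTarget.GAIT_AUTOMATICITY,
    MotorTaskId.LATERAL_WALKING: DeficitTarget.GAIT_AUTOMATICITY,
    MotorTaskId.PACE_SETTER: DeficitTarget.GAIT_VELOCITY,
    MotorTaskId.MARCHING: DeficitTarget.MOVEMENT_AMPLITUDE,
    MotorTaskId.HEEL_KICKING: DeficitTarget.MOVEMENT_AMPLITUDE,
    MotorTaskId.ARM_SWINGS: DeficitTarget.MOVEMENT_AMPLITUDE,
    MotorTaskId.TARGETED_ARM_SWINGS: DeficitTarget.MOVEMENT_AMPLITUDE,
    MotorTaskId.FOOTPRINT_TARGETS: DeficitTarget.STEP_LENGTH,
    MotorTaskId.GAIT_INITIATION: DeficitTarget.TURNING_INITIATION_FOG,
    MotorTaskId.FIGURE_OF_EIGHT: DeficitTarget.TURNING_INITIATION_FOG,
    MotorTaskId.OBSTACLE_COURSE: DeficitTarget.OBJECT_NAVIGATION,
    MotorTaskId.TARGETED_MOVEMENTS: DeficitTarget.POSTURAL_CONTROL,
    MotorTaskId.FLYING_TARGETS: DeficitTarget.POSTURAL_CONTROL,
}

# Allowed parameter keys (and positivity constraints) per motor task.
_PARAM_RULES: dict[MotorTaskId, dict[str, type]] = {
    MotorTaskId.PACE_SETTER: {"target_speed_mps": float},
    MotorTaskId.FOOTPRINT_TARGETS: {"step_length_m": float, "step_width_m": float},
    MotorTaskId.OBSTACLE_COURSE: {"n_pillars": int, "doorway": bool, "lap_length_m": float},
    MotorTaskId.FIGURE_OF_EIGHT: {"loop_length_m": float},
}
_POSITIVE_PARAMS = {"target_speed_mps", "step_length_m", "step_width_m", "lap_length_m", "loop_length_m"}


class MotorTask(BaseModel):
    """One of the 14 motor tasks, with task-specific parameters."""

    id: MotorTaskId
    deficit_target: Optional[DeficitTarget] = None
    params: dict[str, Any] = Field(default_factory=dict)

    def model_post_init(self, __context: Any) -> None:
        if self.deficit_target is None:
            self.deficit_target = _DEFICIT_BY_TASK[self.id]

    @property
    def param_findings(self) -> list[str]:
        """Per-task parameter validation; empty when everything is legal."""
        rules = _PARAM_RULES.get(self.id, {})
        out = []
        for key, val in self.params.items():
            if key not in rules:
                out.append(f"unknown parameter {key!r} for task {self.id.value}")
                continue
            if key in _POSITIVE_PARAMS and not (isinstance(val, (int, float)) and val > 0):
                out.append(f"parameter {key!r} of task {self.id.value} must be > 0, got {val!r}")
        if self.id is MotorTaskId.OBSTACLE_COURSE:
            n = self.params.get("n_pillars")
            if n is not None and (not isinstance(n, int) or n < 0):
                out.append(f"parameter 'n_pillars' must be a non-negative integer, got {n!r}")
        return out


class CognitiveTask(BaseModel):
    """One of the 17 cognitive tasks, labeled with its cognitive domain.

    ``difficulty`` is an ordinal tier; for word-based tasks it is the word
    length (3, 4, or 5 meaning "five or more letters"). Open-ended tasks are
    delivered but never scored, so they are excluded from percent-correct.
    """

    id: str
    domain: CognitiveDomain
    difficulty: int = Field(default=3, ge=1)
    open_ended: bool = False

    @property
    def scoreable(self) -> bool:
        return not self.open_ended


#: the full cognitive catalog: 17 tasks spread over the four domains.
COGNITIVE_CATALOG: dict[str, CognitiveTask] = {
    t.id: t
    for t in [
        # attention
        CognitiveTask(id="spelling_backwards", domain=CognitiveDomain.ATTENTION),
        CognitiveTask(id="serial_subtraction", domain=CognitiveDomain.ATTENTION),
        CognitiveTask(id="months_backwards", domain=CognitiveDomain.ATTENTION),
        CognitiveTask(id="digit_vigilance", domain=CognitiveDomain.ATTENTION),
        # memory
        CognitiveTask(id="word_list_recall", domain=CognitiveDomain.MEMORY),
        CognitiveTask(id="digit_span_forward", domain=CognitiveDomain.MEMORY),
        CognitiveTask(id="digit_span_backward", domain=CognitiveDomain.MEMORY),
        CognitiveTask(id="shopping_list_recall", domain=CognitiveDomain.MEMORY),
        # language
        CognitiveTask(id="odd_one_out", domain=CognitiveDomain.LANGUAGE),
        CognitiveTask(id="category_fluency", domain=CognitiveDomain.LANGUAGE, open_ended=True),
        CognitiveTask(id="letter_fluency", domain=CognitiveDomain.LANGUAGE, open_ended=True),
        CognitiveTask(id="sentence_completion", domain=CognitiveDomain.LANGUAGE),
        CognitiveTask(id="provide_directions", domain=CognitiveDomain.LANGUAGE, open_ended=True),
        # executive function
        CognitiveTask(id="verbal_trail_making", domain=CognitiveDomain.EXECUTIVE_FUNCTION),
        CognitiveTask(id="category_switching", domain=CognitiveDomain.EXECUTIVE_FUNCTION),
        CognitiveTask(id="errand_planning", domain=CognitiveDomain.EXECUTIVE_FUNCTION, open_ended=True),
        CognitiveTask(id="similarities", domain=CognitiveDomain.EXECUTIVE_FUNCTION),
    ]
}

#: the full motor catalog, one entry per task id.
MOTOR_CATALOG: dict[MotorTaskId, MotorTask] = {tid: MotorTask(id=tid) for tid in MotorTaskId}


class ModulePlan(BaseModel):
    """A motor task, an optional concurrent cognitive task, and a duration."""

    motor: MotorTask
    cognitive: Optional[CognitiveTask] = None
    duration_s: float = Field(gt=0)
    order_index: int = Field(ge=0)

    @property
    def is_single_task(self) -> bool:
        return self.cognitive is None


class SessionPlan(BaseModel):
    """An ordered treatment session for one patient.

    ``reference_module_index`` points at the single-task module whose gait
    summary serves as the 100% reference for color coding the others.
    """

    patient_id: str
    modules: list[ModulePlan]
    reference_module_index: Optional[int] = None

    @field_validator("modules")
    @classmethod
    def _non_empty(cls, v: list[ModulePlan]) -> list[ModulePlan]:
        if not v:
            raise ValueError("a session plan needs at least one module")
        return v


class ValidationFinding(BaseModel):
    module_index: Optional[int]
    rule: str
    message: str


def validate_session(plan: SessionPlan) -> list[ValidationFinding]:
    """Check session-level invariants; returns findings instead of raising.

    Rules checked: contiguous unique order indices starting at 0, a
    single-task reference module, positive durations (already enforced by the
    model), and per-task parameter legality.
    """
    findings: list[ValidationFinding] = []
    order = [m.order_index for m in plan.modules]
    if sorted(order) != list(range(len(order))):
        findings.append(
            ValidationFinding(
                module_index=None,
                rule="order_contiguous",
                message=f"order_index values must be unique and contiguous from 0, got {order}",
            )
        )
    ref = plan.reference_module_index
    if ref is not None:
        if not (0 <= ref < len(plan.modules)):
            findings.append(
                ValidationFinding(
                    module_index=ref,
                    rule="reference_in_range",
                    message=f"reference_module_index {ref} outside 0..{len(plan.modules) - 1}",
                )
            )
        elif not plan.modules[ref].is_single_task:
            findings.append(
                ValidationFinding(
                    module_index=ref,
                    rule="reference_single_task",
                    message="reference must be single-task (no cognitive task attached)",
                )
            )
    for i, mod in enumerate(plan.modules):
        for msg in mod.motor.param_findings:
            findings.append(ValidationFinding(module_index=i, rule="motor_params", message=msg))
        if mod.cognitive is not None and mod.cognitive.id not in COGNITIVE_CATALOG:
            findings.append(
                ValidationFinding(
                    module_index=i,
                    rule="cognitive_known",
                    message=f"unknown cognitive task id {mod.cognitive.id!r}",
                )
            )
    return findings


PACE_SETTER_INCREMENT_RANGE = (0.2, 0.3)  # m/s above self-selected comfortable speed


def pace_setter_target(comfortable_speed: float, increment: float) -> float:
    """Target speed for the pace-setter task.

    The target is set 0.2-0.3 m/s above the patient's self-selected
    comfortable speed; increments outside that band are rejected.
    """
    if comfortable_speed <= 0:
        raise ValueError(f"comfortable_speed must be > 0, got {comfortable_speed}")
    lo, hi = PACE_SETTER_INCREMENT_RANGE
    if not (lo <= increment <= hi):
        raise ValueError(f"pace-setter increment must lie in [{lo}, {hi}] m/s, got {increment}")
    return comfortable_speed + increment
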