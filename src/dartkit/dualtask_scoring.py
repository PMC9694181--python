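"""Dual-task interference scoring and clinician color coding.

Every dual-task module is percent-scaled against the single-task warm-up
reference. Motor metrics are color coded green at >= 90% of the reference,
yellow in [80, 90), red below 80; cognitive percent-correct is green at
>= 85%, yellow in [70, 85), red below 70. The dual-task cost (DTC) of a
metric is its percent decline from the reference; a decline of more than
10% flags dual-task impairment (the Timed-Up-and-Go dual-task convention).
Cohort-level single-vs-dual differences use the paired t-test.
"""

from __future__ import annotations

import enum
import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel
from scipy import stats

__all__ = [
    "Color",
    "MetricComparison",
    "InterferenceReport",
    "PairedComparison",
    "percent_of_reference",
    "color_code_motor",
    "color_code_cognitive",
    "dual_task_cost",
    "paired_comparison",
    "build_interference_report",
    "GAIT_METRICS",
    "IMPAIRMENT_CUTOFF_PCT",
]

#: gait metrics scored against the single-task reference (all decline-type:
#: a lower dual-task value is worse)
GAIT_METRICS = ("gait_velocity", "cadence", "step_length", "peak_turn_velocity")

#: percent decline beyond which a gait metric flags dual-task impairment
IMPAIRMENT_CUTOFF_PCT = 10.0

MOTOR_GREEN_PCT = 90.0
MOTOR_YELLOW_PCT = 80.0
COGNITIVE_GREEN_PCT = 85.0
COGNITIVE_YELLOW_PCT = 70.0


class Color(str, enum.Enum):
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"


def percent_of_reference(module_value: float, reference_value: float) -> float:
    """Module value as a percentage of the single-task reference."""
    if not reference_value > 0:
        raise ValueError(f"reference value must be > 0 (valid warm-up required), got {reference_value}")
    return 100.0 * module_value / reference_value


def color_code_motor(pct: float) -> Color:
    """Color for a motor metric given its percent-of-reference.

    Bands partition [0, inf): green >= 90, yellow [80, 90), red < 80.
    """
    if pct < 0:
        raise ValueError(f"percent of reference cannot be negative, got {pct}")
    if pct >= MOTOR_GREEN_PCT:
        return Color.GREEN
    if pct >= MOTOR_YELLOW_PCT:
        return Color.YELLOW
    return Color.RED


def color_code_cognitive(pct_correct: float) -> Color:
    """Color for cognitive percent-correct: green >= 85, yellow [70, 85), red < 70."""
    if not (0.0 <= pct_correct <= 100.0):
        raise ValueError(f"percent correct must lie in [0, 100], got {pct_correct}")
    if pct_correct >= COGNITIVE_GREEN_PCT:
        return Color.GREEN
    if pct_correct >= COGNITIVE_YELLOW_PCT:
        return Color.YELLOW
    return Color.RED


def dual_task_cost(single: float, dual: float) -> tuple[float, bool]:
    """Percent decline from single- to dual-task, and the impairment flag.

    cost = 100 * (single - dual) / single; impairment requires a strict
    > 10% worsening.
    """
    if not single > 0:
        raise ValueError(f"single-task reference must be > 0, got {single}")
    cost = 100.0 * (single - dual) / single
    return cost, cost > IMPAIRMENT_CUTOFF_PCT


class MetricComparison(BaseModel):
    metric: str
    reference_value: float
    module_value: float
    percent_of_reference: float
    color: Color
    dual_task_cost: float
    impaired: bool


class InterferenceReport(BaseModel):
    """Per-module dual-task interference report (the clinician payload)."""

    metrics: list[MetricComparison]
    cognitive_percent_correct: Optional[float] = None
    cognitive_color: Optional[Color] = None
    impaired: bool = False


def build_interference_report(
    reference: dict[str, float],
    module: dict[str, float],
    cognitive_percent_correct: Optional[float] = None,
) -> InterferenceReport:
    """Score one dual-task module against the single-task reference.

    ``reference`` and ``module`` map gait metric names to values; metrics
    missing from either side, or with NaN values, are skipped. The module
    is flagged impaired when any gait metric declines by more than 10%.
    """
    comparisons = []
    for metric in GAIT_METRICS:
        if metric not in reference or metric not in module:
            continue
        ref, val = reference[metric], module[metric]
        if math.isnan(ref) or math.isnan(val):
            continue
        pct = percent_of_reference(val, ref)
        cost, impaired = dual_task_cost(ref, val)
        comparisons.append(
            MetricComparison(
                metric=metric, reference_value=ref, module_value=val,
                percent_of_reference=pct, color=color_code_motor(max(pct, 0.0)),
                dual_task_cost=cost, impaired=impaired,
            )
        )
    cog_color = None
    if cognitive_percent_correct is not None and not math.isnan(cognitive_percent_correct):
        cog_color = color_code_cognitive(cognitive_percent_correct)
    else:
        cognitive_percent_correct = None
    return InterferenceReport(
        metrics=comparisons,
        cognitive_percent_correct=cognitive_percent_correct,
        cognitive_color=cog_color,
        impaired=any(c.impaired for c in comparisons),
    )


class PairedComparison(BaseModel):
    mean_single: float
    mean_dual: float
    mean_difference: float
    t: Optional[float]
    p: Optional[float]
    n: int
    zero_variance: bool = False


def paired_comparison(single: Sequence[float], dual: Sequence[float]) -> PairedComparison:
    """Two-sided paired t-test between single- and dual-task values.

    Pairs must be complete and equally long (n >= 2). A constant
    within-pair difference has zero variance; the t statistic is then
    undefined and the result is flagged instead of raising.
    """
    a = np.asarray(single, dtype=float)
    b = np.asarray(dual, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired samples must be 1-D and equally long, got {a.shape} vs {b.shape}")
    if a.shape[0] < 2:
        raise ValueError("paired comparison needs n >= 2")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise ValueError("paired samples must be pairwise complete (no NaN)")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return PairedComparison(
            mean_single=float(a.mean()), mean_dual=float(b.mean()),
            mean_difference=float(diff.mean()), t=None, p=None,
            n=int(a.shape[0]), zero_variance=True,
        )
    res = stats.ttest_rel(a, b)
    return PairedComparison(
        mean_single=float(a.mean()), mean_dual=float(b.mean()),
        mean_difference=float(diff.mean()),
        t=float(res.statistic), p=float(res.pvalue), n=int(a.shape[0]),
    )
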