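"""Shared fixtures: seeded synthetic traces at the two cohort operating points."""

import pytest

from dartkit.gait_engine import analyze_gait
from dartkit.synth_walker import WalkParams, make_obstacle_course, simulate_walk


@pytest.fixture(scope="session")
def single_task_walk():
    """60-s straight walk at the single-task operating point (trace, truth)."""
    params = WalkParams(speed=1.06, cadence=96.9, duration=60.0, seed=11)
    return simulate_walk(params)


@pytest.fixture(scope="session")
def dual_task_course_walk():
    """60-s obstacle-course walk at the dual-task operating point."""
    params = WalkParams(speed=0.82, cadence=88.2, duration=60.0, seed=12)
    path = make_obstacle_course(n_pillars=3, doorway=True, lap_length=20.0,
                                seed=12, end_turn_peak=146.9)
    return simulate_walk(params, path)


@pytest.fixture(scope="session")
def single_task_summary(single_task_walk):
    trace, _ = single_task_walk
    return analyze_gait(trace)
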