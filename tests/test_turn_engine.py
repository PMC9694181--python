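"""Heading extraction and turn segmentation against analytic yaw profiles
and simulator ground truth."""

import math

import numpy as np
import pytest

from dartkit.kinematics_io import KinematicsTrace, TraceValidationError
from dartkit.synth_walker import (
    CoursePath,
    Straight,
    Turn,
    WalkParams,
    circuit_duration,
    make_figure_of_eight,
    simulate_walk,
)
from dartkit.turn_engine import (
    TurnEvent,
    analyze_turns,
    heading_series,
    segment_turns,
    turn_summary,
)


def _yaw_trace(t, yaw_deg):
    """Trace whose quaternions encode a pure yaw series (degrees)."""
    half = np.radians(yaw_deg) / 2.0
    n = len(t)
    quat = np.column_stack([np.cos(half), np.zeros(n), np.sin(half), np.zeros(n)])
    yr = np.radians(yaw_deg)
    gaze = np.column_stack([np.sin(yr), np.zeros(n), np.cos(yr)])
    wrapped = (np.asarray(yaw_deg) + 180.0) % 360.0 - 180.0
    euler = np.column_stack([np.zeros(n), wrapped, np.zeros(n)])
    return KinematicsTrace(t=t, pos=np.tile([0.0, 1.6, 0.0], (n, 1)),
                           euler=euler, quat=quat, gaze=gaze)


class TestHeadingSeries:
    def test_identity_quaternions_give_constant_zero(self):
        t = np.arange(0, 5, 1 / 60)
        _, yaw = heading_series(_yaw_trace(t, np.zeros_like(t)))
        assert np.allclose(yaw, 0.0, atol=1e-9)

    def test_uniform_rotation_unwraps_to_linear_ramp(self):
        # 90 deg/s for 4 s crosses the ±180° seam; unwrap must keep it linear
        t = np.arange(0, 4 + 1 / 60, 1 / 60)
        _, yaw = heading_series(_yaw_trace(t, 90.0 * t), lowpass_hz=None)
        assert yaw[0] == pytest.approx(0.0, abs=1e-9)
        assert yaw[-1] == pytest.approx(360.0, abs=1e-6)
        assert np.max(np.abs(np.diff(yaw))) < 180.0
        np.testing.assert_allclose(yaw, 90.0 * t, atol=1e-6)

    def test_euler_and_quaternion_yaw_agree_on_simulator_output(self):
        trace, _ = simulate_walk(
            WalkParams(speed=1.0, cadence=100.0, duration=20.0, seed=6),
            make_figure_of_eight(4.0, 120.0),
        )
        _, yaw_q = heading_series(trace, lowpass_hz=None)
        yaw_e = np.degrees(np.unwrap(np.radians(trace.euler[:, 1])))
        np.testing.assert_allclose(yaw_q, yaw_e, atol=1e-6)

    def test_non_unit_quaternion_rejected(self):
        t = np.arange(0, 2, 1 / 60)
        trace = _yaw_trace(t, np.zeros_like(t))
        trace.quat[5] *= 1.5
        with pytest.raises(TraceValidationError):
            heading_series(trace)


class TestSegmentTurns:
    def test_constant_heading_yields_no_turns(self):
        t = np.arange(0, 10, 1 / 60)
        assert segment_turns(t, np.full_like(t, 30.0)) == []

    def test_single_180_turn_at_constant_rate(self):
        # 5 s still, 180° at 90 deg/s, 5 s still
        fs = 60
        t = np.arange(0, 12, 1 / fs)
        yaw = np.clip((t - 5.0) * 90.0, 0.0, 180.0)
        events = segment_turns(t, yaw)
        assert len(events) == 1
        e = events[0]
        assert e.magnitude == pytest.approx(180.0, abs=2.0)
        assert e.duration == pytest.approx(2.0, abs=0.05)
        assert e.mean_velocity == pytest.approx(90.0, rel=0.03)
        assert e.peak_velocity == pytest.approx(90.0, rel=0.03)

    def test_figure_of_eight_circuit_has_equal_left_right_turns(self):
        path = make_figure_of_eight(4.0, 150.0)
        speed = 1.0
        dur = circuit_duration(path, speed) + 1.0
        trace, _ = simulate_walk(WalkParams(speed=speed, cadence=100.0, duration=dur, seed=7), path)
        events, summary = analyze_turns(trace)
        left = [e for e in events if e.magnitude > 0]
        right = [e for e in events if e.magnitude < 0]
        assert summary.n_turns == 4
        assert len(left) == len(right) == 2
        total = sum(abs(e.magnitude) for e in events)
        assert total == pytest.approx(720.0, abs=40.0)

    def test_mirror_symmetry(self):
        path = make_figure_of_eight(4.0, 150.0)
        trace, _ = simulate_walk(WalkParams(speed=1.0, cadence=100.0, duration=30.0, seed=8), path)
        t, yaw = heading_series(trace)
        fwd = segment_turns(t, yaw)
        mirrored = segment_turns(t, -yaw)
        assert len(fwd) == len(mirrored)
        for a, b in zip(fwd, mirrored):
            assert b.magnitude == pytest.approx(-a.magnitude, abs=1e-9)
            assert b.duration == pytest.approx(a.duration, abs=1e-9)
            assert b.peak_velocity == pytest.approx(a.peak_velocity, rel=1e-9)

    def test_events_are_disjoint_ordered_and_in_bounds(self):
        path = make_figure_of_eight(3.0, 140.0)
        trace, _ = simulate_walk(WalkParams(speed=1.1, cadence=105.0, duration=45.0, seed=9), path)
        t, yaw = heading_series(trace)
        events = segment_turns(t, yaw)
        assert len(events) >= 2
        for e in events:
            assert t[0] <= e.t_on < e.t_off <= t[-1]
        for a, b in zip(events, events[1:]):
            assert a.t_off <= b.t_on

    def test_raising_threshold_never_increases_turn_count(self):
        path = make_figure_of_eight(4.0, 150.0)
        trace, _ = simulate_walk(WalkParams(speed=1.0, cadence=100.0, duration=40.0, seed=10), path)
        t, yaw = heading_series(trace)
        counts = [len(segment_turns(t, yaw, rate_threshold=thr))
                  for thr in (5.0, 15.0, 40.0, 80.0, 200.0)]
        assert counts == sorted(counts, reverse=True)

    def test_sub_minimum_angle_changes_are_not_turns(self):
        # a 30° heading change is below the 45° minimum
        fs = 60
        t = np.arange(0, 8, 1 / fs)
        yaw = np.clip((t - 3.0) * 60.0, 0.0, 30.0)
        assert segment_turns(t, yaw) == []


class TestTurnSummary:
    def test_empty_input_gives_zero_turns_and_nan_sentinels(self):
        s = turn_summary([])
        assert s.n_turns == 0
        assert math.isnan(s.mean_turn_time)
        assert math.isnan(s.peak_turn_velocity)

    def test_peak_is_max_over_events(self):
        events = [
            TurnEvent(t_on=0.0, t_off=2.0, magnitude=180.0, mean_velocity=90.0, peak_velocity=100.0),
            TurnEvent(t_on=5.0, t_off=6.5, magnitude=-120.0, mean_velocity=80.0, peak_velocity=150.0),
        ]
        s = turn_summary(events)
        assert s.n_turns == 2
        assert s.peak_turn_velocity == pytest.approx(150.0)
        assert s.mean_turn_time == pytest.approx((2.0 + 1.5) / 2)

    def test_commanded_peak_recovered_within_10_deg_s(self):
        segs = [Straight(5.0)]
        for i in range(4):
            segs += [Turn(180.0 if i % 2 == 0 else -180.0, 187.9), Straight(5.0)]
        trace, _ = simulate_walk(
            WalkParams(speed=1.06, cadence=96.9, duration=45.0, seed=11),
            CoursePath(segments=segs),
        )
        _, summary = analyze_turns(trace)
        assert summary.n_turns == 4
        assert summary.peak_turn_velocity == pytest.approx(187.9, abs=10.0)
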