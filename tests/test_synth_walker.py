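"""The synthetic head-trajectory generator: parameter resolution, course
geometry, determinism, freezing episodes and the paired-cohort sampler."""

import numpy as np
import pytest

from dartkit.gait_engine import analyze_gait, detect_steps, gait_velocity
from dartkit.kinematics_io import write_trace
from dartkit.synth_walker import (
    DUAL_TASK_POINT,
    SINGLE_TASK_POINT,
    CoursePath,
    Stop,
    Straight,
    Turn,
    WalkParams,
    circuit_duration,
    make_figure_of_eight,
    make_obstacle_course,
    simulate_cohort,
    simulate_walk,
)


class TestWalkParams:
    def test_third_parameter_is_implied_exactly(self):
        p = WalkParams(speed=1.06, cadence=96.9)
        assert p.speed == pytest.approx(p.step_length * p.cadence / 60.0, abs=1e-12)
        q = WalkParams(step_length=0.63, cadence=96.9)
        assert q.speed == pytest.approx(0.63 * 96.9 / 60.0, abs=1e-12)

    def test_exactly_two_of_three_required(self):
        with pytest.raises(ValueError, match="exactly two"):
            WalkParams(speed=1.0)
        with pytest.raises(ValueError, match="exactly two"):
            WalkParams(speed=1.0, cadence=100.0, step_length=0.6)

    def test_implausible_step_length_rejected(self):
        with pytest.raises(ValueError, match="step length"):
            WalkParams(speed=2.0, cadence=60.0)  # implies 2.0 m


class TestSimulateWalk:
    def test_same_seed_gives_byte_identical_csv(self):
        a, _ = simulate_walk(WalkParams(speed=1.0, cadence=100.0, duration=10.0, seed=42))
        b, _ = simulate_walk(WalkParams(speed=1.0, cadence=100.0, duration=10.0, seed=42))
        assert write_trace(a) == write_trace(b)

    def test_different_seeds_differ(self):
        a, _ = simulate_walk(WalkParams(speed=1.0, cadence=100.0, duration=5.0, seed=1))
        b, _ = simulate_walk(WalkParams(speed=1.0, cadence=100.0, duration=5.0, seed=2))
        assert write_trace(a) != write_trace(b)

    def test_zero_noise_zero_bob_gives_no_steps_and_exact_speed(self):
        p = WalkParams(speed=1.0, cadence=100.0, duration=10.0, seed=0,
                       bob_amplitude=0.0, sway_amplitude=0.0, noise_sd=0.0,
                       yaw_noise_sd=0.0)
        trace, _ = simulate_walk(p)
        assert detect_steps(trace).n_steps == 0
        assert gait_velocity(trace) == pytest.approx(1.0, abs=0.01)

    def test_ground_truth_step_times_match_detected_count(self):
        trace, truth = simulate_walk(WalkParams(speed=1.0, cadence=100.0, duration=30.0, seed=3))
        detected = detect_steps(trace)
        in_window = truth.step_times[(truth.step_times >= trace.t[0] + 0.5)
                                     & (truth.step_times <= trace.t[-1] - 0.5)]
        assert abs(detected.n_steps - len(in_window)) <= 1

    def test_fog_episode_freezes_horizontal_progression(self):
        path = CoursePath(segments=[Straight(100.0)], fog_episodes=[(5.0, 3.0)])
        trace, truth = simulate_walk(WalkParams(speed=1.0, cadence=100.0, duration=15.0, seed=4), path)
        mask = (trace.t >= 5.2) & (trace.t <= 7.8)
        drift = np.ptp(trace.pos[mask][:, [0, 2]], axis=0)
        assert np.all(drift < 0.05)  # only jitter remains
        assert truth.fog_intervals == [(5.0, 3.0)]

    def test_scripted_stop_segment_freezes_too(self):
        path = CoursePath(segments=[Straight(5.0), Stop(4.0), Straight(50.0)])
        trace, _ = simulate_walk(WalkParams(speed=1.0, cadence=100.0, duration=15.0, seed=5), path)
        mask = (trace.t >= 5.5) & (trace.t <= 8.5)
        assert np.ptp(trace.pos[mask][:, 2]) < 0.05


class TestCourses:
    def test_obstacle_course_layout(self):
        path = make_obstacle_course(n_pillars=3, doorway=True, lap_length=20.0, seed=0)
        turns = [s for s in path.segments if isinstance(s, Turn)]
        end_turns = [s for s in turns if abs(s.angle) == 180.0]
        sidestep_turns = [s for s in turns if abs(s.angle) < 45.0]
        assert path.loop
        assert len(end_turns) == 2
        assert len(sidestep_turns) == 4 * 3  # four sub-threshold deviations per pillar

    def test_zero_pillars_no_doorway_is_a_plain_loop(self):
        path = make_obstacle_course(n_pillars=0, doorway=False, lap_length=20.0, seed=0)
        kinds = [type(s).__name__ for s in path.segments]
        assert kinds == ["Straight", "Turn", "Straight", "Turn"]

    def test_same_seed_gives_identical_course(self):
        assert make_obstacle_course(3, True, 20.0, seed=9) == make_obstacle_course(3, True, 20.0, seed=9)

    def test_too_short_lap_rejected(self):
        with pytest.raises(ValueError, match="lap_length"):
            make_obstacle_course(1, False, 1.5)

    def test_figure_of_eight_balances_turn_directions(self):
        path = make_figure_of_eight(4.0, 150.0)
        angles = [s.angle for s in path.segments if isinstance(s, Turn)]
        assert sorted(angles) == [-180.0, -180.0, 180.0, 180.0]

    def test_from_waypoints_square_loop(self):
        path = CoursePath.from_waypoints([(0, 0), (0, 5), (5, 5), (5, 0)],
                                         peak_turn_velocity=120.0, loop=True)
        turns = [s for s in path.segments if isinstance(s, Turn)]
        assert len(turns) == 4
        assert all(abs(abs(t.angle) - 90.0) < 1e-9 for t in turns)
        corners = path.waypoints()
        assert len(corners) == 5  # closes back on the start

    def test_duplicate_waypoints_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            CoursePath.from_waypoints([(0, 0), (0, 0), (1, 1)])

    def test_circuit_duration_accounts_for_turns(self):
        path = make_figure_of_eight(4.0, 150.0)
        dur = circuit_duration(path, 1.0)
        straights = 4 * 4.0 / 1.0
        turns = 4 * (180.0 / 150.0 + 0.2)
        assert dur == pytest.approx(straights + turns)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("point", [SINGLE_TASK_POINT, DUAL_TASK_POINT])
    def test_straight_walk_recovery_within_5pct(self, point):
        p = WalkParams(speed=point["gait_velocity"][0], cadence=point["cadence"][0],
                       duration=60.0, seed=21)
        trace, truth = simulate_walk(p)
        s = analyze_gait(trace)
        assert s.gait_velocity == pytest.approx(truth.speed, rel=0.05)
        assert s.cadence == pytest.approx(truth.cadence, rel=0.05)
        assert s.step_length == pytest.approx(truth.step_length, rel=0.05)


class TestSimulateCohort:
    def test_sample_means_within_2_se_of_commanded(self):
        n = 47
        df = simulate_cohort(n, seed=7)
        for metric, (mean, sd) in SINGLE_TASK_POINT.items():
            se = sd / np.sqrt(n)
            assert abs(df[f"{metric}_single"].mean() - mean) < 2 * se
        for metric, (mean, sd) in DUAL_TASK_POINT.items():
            se = sd / np.sqrt(n)
            assert abs(df[f"{metric}_dual"].mean() - mean) < 2 * se

    def test_perfect_correlation_equal_sds_gives_constant_difference(self):
        point_a = {"gait_velocity": (1.0, 0.1)}
        point_b = {"gait_velocity": (0.8, 0.1)}
        df = simulate_cohort(10, point_a, point_b, correlation=1.0, seed=1)
        diff = df["gait_velocity_single"] - df["gait_velocity_dual"]
        assert np.allclose(diff, 0.2, atol=1e-7)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError, match="correlation"):
            simulate_cohort(10, correlation=1.5)

    def test_mismatched_metric_sets_rejected(self):
        with pytest.raises(ValueError, match="share metrics"):
            simulate_cohort(10, {"a": (1, 0.1)}, {"b": (1, 0.1)})
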