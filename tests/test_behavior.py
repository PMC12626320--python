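import numpy as np
import pytest

from conftest import make_loop_trajectory, make_trajectory
from wormtrack.behavior import (
    BehaviorConfig,
    average_speed,
    bending_angle,
    classify_direction,
    curvature_profile,
    detect_omega_turns,
    detect_rolls,
    instantaneous_speed,
    per_second_mean_speed,
    roll_frequency,
    smooth_speed,
    summarize_behavior,
)
from wormtrack.errors import ConfigError, InsufficientDataError, ZeroIntervalError
from wormtrack.geometry import BoundingBox

CFG = BehaviorConfig()


class TestSpeed:
    def test_three_four_five_displacement(self):
        traj = make_trajectory([0, 3], [0, 4], fps=1.0)
        assert instantaneous_speed(traj) == pytest.approx([5.0])

    def test_constant_position_gives_zeros(self):
        traj = make_trajectory(np.zeros(10), np.zeros(10))
        assert np.all(instantaneous_speed(traj) == 0.0)

    def test_circle_speed_matches_arc_rate(self):
        # radius R at angular rate w -> speed R*w everywhere (1% at fine sampling)
        R, w, fps = 40.0, 1.0, 200.0
        t = np.arange(0, 4.0, 1 / fps)
        traj = make_trajectory(R * np.cos(w * t), R * np.sin(w * t), fps=fps)
        v = instantaneous_speed(traj)
        assert np.allclose(v, R * w, rtol=0.01)

    def test_duplicate_timestamps_rejected(self):
        traj = make_trajectory([0, 1, 2], [0, 0, 0])
        traj.t = np.array([0.0, 0.0, 1.0])
        with pytest.raises(ZeroIntervalError):
            instantaneous_speed(traj)

    def test_average_speed_equal_duration_segments(self):
        # 10 s at 2 px/s then 10 s at 4 px/s -> 3 px/s
        fps = 10.0
        x1 = np.arange(0, 20, 2 / fps)
        x2 = x1[-1] + 2 / fps + np.arange(0, 40, 4 / fps)
        traj = make_trajectory(np.concatenate([x1, x2]), np.zeros(len(x1) + len(x2)), fps=fps)
        assert average_speed(traj) == pytest.approx(3.0, rel=0.01)

    def test_average_speed_equals_independent_resummation(self, rng):
        steps = rng.normal(0, 2, size=(100, 2))
        pts = np.cumsum(steps, axis=0)
        traj = make_trajectory(pts[:, 0], pts[:, 1], fps=25.0)
        expected = np.hypot(*np.diff(pts, axis=0).T).sum() / (traj.t[-1] - traj.t[0])
        assert average_speed(traj) == pytest.approx(expected, abs=1e-9)

    def test_average_speed_invariant_under_uniform_subsampling(self):
        traj = make_trajectory(np.arange(100) * 2.0, np.zeros(100), fps=25.0)
        sub = make_trajectory(traj.x[::4], traj.y[::4], fps=25.0 / 4)
        assert average_speed(traj) == pytest.approx(average_speed(sub), abs=1e-9)

    def test_per_second_mean_uniform_motion(self):
        traj = make_trajectory(np.arange(100) * 2.0, np.zeros(100), fps=25.0)
        assert per_second_mean_speed(traj) == pytest.approx(50.0, rel=1e-6)

    def test_per_second_mean_matches_binning_oracle(self, rng):
        # irregular sampling: brute-force per-bin recomputation
        t = np.sort(rng.uniform(0, 5, size=120))
        t += np.arange(120) * 1e-6  # ensure strictly increasing
        x = np.cumsum(rng.normal(0, 1, size=120))
        y = np.cumsum(rng.normal(0, 1, size=120))
        traj = make_trajectory(x, y, fps=25.0)
        traj.t = t - t[0]
        bins = []
        start = 0.0
        rel = traj.t
        while start < rel[-1]:
            idx = np.flatnonzero((rel >= start) & (rel <= start + 1.0))
            if len(idx) >= 2:
                span = rel[idx[-1]] - rel[idx[0]]
                trailing_partial = start + 1.0 > rel[-1] and (rel[-1] - start) < 0.5
                if span > 0 and not trailing_partial:
                    ds = np.hypot(np.diff(x[idx]), np.diff(y[idx])).sum()
                    bins.append(ds / span)
            start += 1.0
        assert per_second_mean_speed(traj) == pytest.approx(np.mean(bins), abs=1e-12)

    def test_short_trajectory_rejected(self):
        traj = make_trajectory([0, 1, 2], [0, 0, 0], fps=25.0)  # spans 0.08 s
        with pytest.raises(InsufficientDataError):
            per_second_mean_speed(traj)


class TestSmoothing:
    def test_constant_series_is_fixed_point(self):
        s = np.full(20, 3.0)
        assert np.array_equal(smooth_speed(s, 5), s)

    def test_window_one_is_identity(self, rng):
        s = rng.random(15)
        assert np.array_equal(smooth_speed(s, 1), s)

    def test_unit_impulse_kernel(self):
        s = np.zeros(9)
        s[4] = 1.0
        out = smooth_speed(s, 3)
        assert out[3:6] == pytest.approx([1 / 3, 1 / 3, 1 / 3])
        assert out[0] == 0.0 and out[-1] == 0.0

    def test_even_window_rejected(self):
        with pytest.raises(ConfigError):
            smooth_speed(np.ones(10), 4)


class TestDirection:
    def test_rightward_motion_with_rightward_axis_is_forward(self):
        traj = make_trajectory(np.arange(50) * 2.0, np.zeros(50))
        axis = np.tile([1.0, 0.0], (50, 1))
        assert np.all(classify_direction(traj, CFG, axis) == "forward")

    def test_flipped_axis_is_backward(self):
        traj = make_trajectory(np.arange(50) * 2.0, np.zeros(50))
        axis = np.tile([-1.0, 0.0], (50, 1))
        assert np.all(classify_direction(traj, CFG, axis) == "backward")

    def test_slow_motion_is_stationary(self):
        traj = make_trajectory(np.arange(50) * 0.001, np.zeros(50))
        axis = np.tile([1.0, 0.0], (50, 1))
        assert np.all(classify_direction(traj, CFG, axis) == "stationary")

    def test_simulated_reversals_recovered(self):
        from wormtrack.simulate import SimConfig, simulate

        accs = []
        for seed in range(3):
            truth = simulate(SimConfig(seed=seed, reversal_rate=0.15))
            for w, traj in truth.trajectories.items():
                states = classify_direction(traj, CFG, truth.orientations[w])
                accs.append(np.mean(states == truth.true_states(w)))
        assert min(accs) >= 0.95

    def test_orientation_shape_mismatch_rejected(self):
        from wormtrack.errors import InconsistentInputError

        traj = make_trajectory(np.arange(10), np.zeros(10))
        with pytest.raises(InconsistentInputError):
            classify_direction(traj, CFG, np.ones((5, 2)))


class TestBendingAngle:
    def test_square_box_is_ninety_degrees(self):
        assert bending_angle(BoundingBox(0, 0, 10, 10), CFG) == pytest.approx(90.0)

    def test_wide_symmetric_case_is_ninety_degrees(self):
        # w = 2h in the wide branch: 2*arctan(2h/w) = 2*arctan(1) = 90
        assert bending_angle(BoundingBox(0, 0, 20, 10), CFG) == pytest.approx(90.0)

    def test_tall_box_angle(self):
        # w=10, h=40: 2*arctan(0.25) ~ 28.07 deg
        assert bending_angle(BoundingBox(0, 0, 10, 40), CFG) == pytest.approx(
            np.degrees(2 * np.arctan(0.25)), abs=1e-9
        )
        assert bending_angle(BoundingBox(0, 0, 10, 40), CFG) == pytest.approx(28.07, abs=0.01)

    def test_elongated_box_is_straight(self):
        cfg = BehaviorConfig(straightness_ratio=4.0)
        assert bending_angle(BoundingBox(0, 0, 50, 10), cfg) is None
        assert bending_angle(BoundingBox(0, 0, 10, 50), cfg) is None

    def test_straightness_cutoff_respected(self):
        cfg = BehaviorConfig(straightness_ratio=5.0)
        assert bending_angle(BoundingBox(0, 0, 10, 40), cfg) is not None


class TestRolls:
    def test_constant_aspect_ratio_no_events(self):
        traj = make_trajectory(np.arange(50), np.zeros(50))
        assert detect_rolls(traj, CFG) == []

    def test_single_step_change_one_event(self):
        w = np.full(50, 10.0)
        w[25:] = 10.0 + 2 * CFG.theta_roll * 10.0  # ratio jumps by 2*theta_roll
        traj = make_trajectory(np.arange(50), np.zeros(50), w=w)
        events = detect_rolls(traj, CFG)
        assert len(events) == 1
        assert events[0].t == pytest.approx(traj.t[25])
        assert events[0].statistic > CFG.theta_roll

    def test_k_separated_episodes_give_k_events(self):
        fps = 25.0
        n = 500
        w = np.full(n, 10.0)
        starts = [50, 150, 250, 350, 450]  # separated by 4 s >> refractory
        for s in starts:
            w[s : s + 4] = 20.0  # aspect excursion of amplitude 1.0
        traj = make_trajectory(np.arange(n), np.zeros(n), fps=fps, w=w)
        assert len(detect_rolls(traj, CFG)) == len(starts)

    def test_roll_frequency_arithmetic(self):
        traj = make_trajectory(np.arange(751), np.zeros(751), fps=25.0)  # 30 s
        events = [type("E", (), {"kind": "roll"})() for _ in range(6)]
        assert roll_frequency(events, traj) == pytest.approx(0.2)

    def test_no_events_zero_frequency(self):
        traj = make_trajectory(np.arange(100), np.zeros(100), fps=25.0)
        assert roll_frequency([], traj) == 0.0


class TestCurvature:
    def test_straight_motion_zero_curvature(self):
        traj = make_trajectory(np.arange(100) * 2.0, np.arange(100) * 1.0)
        k = curvature_profile(traj)
        assert np.nanmax(np.abs(k)) < 1e-9

    @pytest.mark.parametrize("radius", [5.0, 20.0, 100.0, 500.0])
    def test_circle_curvature_recovery(self, radius):
        # >= 100 samples per revolution: |k| = 1/R within 2%
        n = 200
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        traj = make_trajectory(radius * np.cos(ang), radius * np.sin(ang), fps=25.0)
        k = curvature_profile(traj)
        interior = k[2:-2]
        assert np.allclose(np.abs(interior), 1.0 / radius, rtol=0.02)

    def test_sign_convention_counter_clockwise_positive_image_frame(self):
        # y grows downward in image coordinates: a path turning toward +y
        # (screen-down) from +x is a positive cross product z-component
        n = 200
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        ccw = make_trajectory(20 * np.cos(ang), 20 * np.sin(ang), fps=25.0)
        mirrored = make_trajectory(20 * np.cos(ang), -20 * np.sin(ang), fps=25.0)
        k1 = curvature_profile(ccw)[2:-2]
        k2 = curvature_profile(mirrored)[2:-2]
        assert np.allclose(k1, -k2, rtol=1e-6)
        assert np.all(k1 > 0) or np.all(k1 < 0)

    def test_standstill_yields_undefined_marker(self):
        x = np.concatenate([np.arange(10), np.full(5, 9.0), 9 - np.arange(10)])
        traj = make_trajectory(x, np.zeros(len(x)), fps=1.0)
        k = curvature_profile(traj, min_speed=0.1)
        assert np.isnan(k[12])

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            curvature_profile(make_trajectory([0, 1], [0, 0]))


class TestOmegaTurns:
    def test_straight_trajectory_no_events(self):
        traj = make_trajectory(np.arange(200) * 2.0, np.zeros(200))
        assert detect_omega_turns(traj, CFG) == []

    def test_single_loop_one_event_near_apex(self):
        # 300-degree loop, radius 10 (1/r = 0.1 > theta_curve), straight flanks
        traj = make_loop_trajectory(radius=10.0)
        events = detect_omega_turns(traj, CFG)
        assert len(events) == 1
        # apex: the arc's midpoint in time
        arc_start = 200.0 / 50.0
        arc_mid = arc_start + (np.radians(300) * 10.0 / 50.0) / 2
        assert abs(events[0].t - arc_mid) <= CFG.curvature_window
        assert events[0].statistic >= CFG.theta_curve

    def test_two_separated_loops_two_events(self):
        traj = make_loop_trajectory(radius=10.0, n_loops=2, gap=150.0)
        assert len(detect_omega_turns(traj, CFG)) == 2

    def test_gentle_arc_below_threshold_ignored(self):
        traj = make_loop_trajectory(radius=50.0)  # 1/r = 0.02 < theta_curve
        assert detect_omega_turns(traj, CFG) == []

    def test_window_longer_than_trajectory_rejected(self):
        traj = make_trajectory(np.arange(10), np.zeros(10), fps=1.0)
        with pytest.raises(ConfigError):
            detect_omega_turns(traj, BehaviorConfig(curvature_window=100.0))


class TestInvariances:
    def test_event_counts_invariant_to_rigid_motion(self):
        base = make_loop_trajectory(radius=10.0)
        w = np.full(len(base), 10.0)
        w[100:104] = 20.0
        base.w = w
        n_rolls = len(detect_rolls(base, CFG))
        n_turns = len(detect_omega_turns(base, CFG))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy = rot @ np.stack([base.x, base.y]) + np.array([[500.0], [-120.0]])
        moved = make_trajectory(xy[0], xy[1], fps=base.fps, w=base.w, h=base.h)
        assert len(detect_rolls(moved, CFG)) == n_rolls
        assert len(detect_omega_turns(moved, CFG)) == n_turns


class TestSummary:
    def test_uniform_forward_motion(self):
        traj = make_trajectory(np.arange(200) * 2.0, np.zeros(200))
        axis = np.tile([1.0, 0.0], (200, 1))
        s = summarize_behavior(traj, CFG, orientation=axis)
        assert s.fraction_forward == pytest.approx(1.0)
        assert s.roll_frequency == 0.0
        assert s.omega_turn_count == 0
        assert s.mean_speed == pytest.approx(50.0, rel=1e-6)

    def test_stationary_worm_all_quiet(self):
        traj = make_trajectory(np.zeros(200), np.zeros(200))
        s = summarize_behavior(traj, CFG)
        assert s.fraction_stationary == pytest.approx(1.0)
        assert s.roll_frequency == 0.0 and s.omega_turn_count == 0

    def test_fractions_sum_to_one(self, rng):
        pts = np.cumsum(rng.normal(0, 2, size=(300, 2)), axis=0)
        traj = make_trajectory(pts[:, 0], pts[:, 1])
        s = summarize_behavior(traj, CFG)
        total = s.fraction_forward + s.fraction_backward + s.fraction_stationary
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_physical_calibration_scales_speed(self):
        traj = make_trajectory(np.arange(200) * 2.0, np.zeros(200))
        s = summarize_behavior(traj, BehaviorConfig(pixel_scale=2.5))
        assert s.mean_speed_physical == pytest.approx(2.5 * s.mean_speed)
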