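"""Error trajectories and the two release-timing measures."""

from __future__ import annotations

import numpy as np
import pytest

from skittles.config import TaskConfig
from skittles.synth import NoiseModel, StrategyParams, generate_arm_trajectory
from skittles.task_model import ReleaseState, score_throw
from skittles.timing import (
    ArmTrajectory,
    ErrorTrajectory,
    analyze_throw,
    compute_timing_measures,
    error_trajectory,
    timing_error,
    timing_measures_invariant,
    timing_window,
    _subthreshold_runs,
)


def make_et(error, threshold=1.1, sample_rate=1000.0):
    """Constructed error trajectory from a raw error series (ms-spaced)."""
    error = np.asarray(error, dtype=float)
    runs = _subthreshold_runs(error, threshold)
    return ErrorTrajectory(
        time=np.arange(error.size) / sample_rate,
        error=error,
        post_hit=np.zeros(error.size, bool),
        ideal_index=int(np.argmin(error)),
        subthreshold_intervals=runs,
        success_threshold=threshold,
    )


def vshape(n, minimum_at, depth=0.0, slope=0.01):
    i = np.arange(n)
    return depth + slope * np.abs(i - minimum_at)


@pytest.fixture(scope="module")
def swing_traj():
    sp = StrategyParams(60.0, 130.0, 0.4, planned_release_fraction=0.6)
    nm = NoiseModel(0.0, 0.0, 0.0, seed=3)
    return generate_arm_trajectory(sp, nm, TaskConfig(target_center=(25.0, 80.0)))


class TestErrorTrajectory:
    def test_frozen_state_gives_constant_error(self, default_config):
        n = 200
        traj = ArmTrajectory(
            time=np.arange(n) / 1000.0, angle=np.full(n, 95.0), release_index=100
        )
        et = error_trajectory(traj, default_config)
        assert np.all(et.error == et.error[0])

    def test_release_sample_matches_scored_throw_bitwise(self, default_config, swing_traj):
        et = error_trajectory(swing_traj, default_config)
        res = score_throw(swing_traj.release_state(), default_config)
        assert et.error[swing_traj.release_index] == res.error

    def test_too_short_trajectory_rejected(self, default_config):
        traj = ArmTrajectory(time=np.arange(10) / 1000.0, angle=np.zeros(10), release_index=5)
        with pytest.raises(ValueError):
            error_trajectory(traj, default_config)

    def test_trajectory_through_solution_state_dips_subthreshold(self, default_config):
        # steer the sweep through a state whose throw error is (near) zero
        from skittles.task_model import ball_position, launch_to_flight_params, lever_state_to_launch

        state = ReleaseState(95.0, 400.0)
        la = lever_state_to_launch(state, default_config)
        target = ball_position(launch_to_flight_params(la, default_config), 0.3)
        cfg = default_config.replace(target_center=(float(target[0]), float(target[1])))
        from skittles.synth import strategy_through_state

        sp = strategy_through_state(95.0, 400.0, 0.55, 0.4)
        traj = generate_arm_trajectory(sp, NoiseModel(0.0, 0.0, 0.0, seed=0), cfg)
        et = error_trajectory(traj, cfg)
        assert et.error.min() < cfg.success_threshold


class TestTimingError:
    def test_release_at_global_minimum_is_zero(self):
        et = make_et(vshape(600, 300))
        assert timing_error(et, 300, "global_min") == 0.0

    def test_vshape_offset_release(self):
        # minimum at 300 ms, release at 250 ms -> 50 ms timing error
        et = make_et(vshape(600, 300))
        assert timing_error(et, 250, "global_min") == pytest.approx(50.0)
        assert timing_error(et, 250, "nearest_crossing") == pytest.approx(50.0)

    def test_two_crossings_nearest_is_used(self):
        # sub-threshold minima at 200 ms and 400 ms; release at 360 ms
        e = np.minimum(vshape(600, 200, slope=0.02), vshape(600, 400, slope=0.02))
        et = make_et(e)
        assert len(et.subthreshold_intervals) == 2
        assert timing_error(et, 360, "nearest_crossing") == pytest.approx(40.0)
        # the global minimum rule ignores proximity (tie resolves to first)
        assert timing_error(et, 360, "global_min") == pytest.approx(160.0)

    def test_no_crossing_falls_back_to_global_min(self):
        et = make_et(vshape(500, 123, depth=5.0))
        assert not et.subthreshold_intervals
        assert timing_error(et, 100, "nearest_crossing") == pytest.approx(23.0)

    def test_window_midpoint_rule(self):
        e = vshape(600, 300, slope=0.02)  # below 1.1 within +-54 samples
        et = make_et(e)
        lo, hi = et.subthreshold_intervals[0]
        mid = 0.5 * (lo + hi)
        assert timing_error(et, 250, "window_midpoint") == pytest.approx(abs(250 - mid))

    def test_shift_release_shifts_error_linearly(self):
        et = make_et(vshape(600, 300))
        base = timing_error(et, 250)
        for k in (1, 5, 17):
            assert timing_error(et, 250 - k) == pytest.approx(base + k)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            timing_error(make_et(vshape(100, 50)), 10, "nearest")


class TestTimingWindow:
    def test_no_subthreshold_sample_gives_zero(self):
        et = make_et(np.full(400, 3.0))
        assert timing_window(et, 200) == 0.0

    def test_fifty_samples_give_fifty_ms(self):
        e = np.full(400, 9.0)
        e[100:150] = 0.5  # samples 100..149 inclusive below threshold
        et = make_et(e)
        assert timing_window(et, 120) == pytest.approx(50.0)

    def test_segment_selection_picks_nearest_run(self):
        e = np.full(600, 9.0)
        e[100:130] = 0.5  # 30 ms run
        e[400:480] = 0.5  # 80 ms run
        et = make_et(e)
        assert timing_window(et, 140) == pytest.approx(30.0)
        assert timing_window(et, 380) == pytest.approx(80.0)

    def test_monotone_in_success_threshold(self, default_config, swing_traj):
        windows = []
        for thr in (0.5, 1.1, 2.0):
            cfg = default_config.replace(
                success_threshold=thr, miss_threshold=max(2.5, thr + 0.1)
            )
            et = error_trajectory(swing_traj, cfg)
            windows.append(timing_window(et, swing_traj.release_index))
        assert windows == sorted(windows)


class TestMeasuresBundle:
    def test_measures_consistent_with_parts(self, default_config, swing_traj):
        et = error_trajectory(swing_traj, default_config)
        m = compute_timing_measures(et, swing_traj.release_index)
        assert m.timing_error == timing_error(et, swing_traj.release_index)
        assert m.timing_window == timing_window(et, swing_traj.release_index)
        assert m.reference_rule == "nearest_crossing"

    def test_analyze_throw_matches_score_throw(self, default_config, swing_traj):
        result, measures = analyze_throw(swing_traj, default_config)
        res = score_throw(swing_traj.release_state(), default_config)
        assert result.error == res.error
        assert result.category == res.category
        assert measures.timing_error >= 0 and measures.timing_window >= 0


class TestCoordinateInvariance:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_polar_and_cartesian_measures_identical(self, default_config, seed):
        sp = StrategyParams(55.0 + 3 * seed, 140.0 - 2 * seed, 0.35 + 0.02 * seed)
        nm = NoiseModel(10.0, 1.5, 20.0, seed=seed)
        traj = generate_arm_trajectory(sp, nm, default_config)
        polar, cart = timing_measures_invariant(traj, default_config)
        assert polar.timing_error == cart.timing_error
        assert polar.timing_window == cart.timing_window

    def test_frozen_trajectory_full_or_empty_window(self, default_config):
        n = 300
        traj = ArmTrajectory(
            time=np.arange(n) / 1000.0, angle=np.full(n, 95.0), release_index=150
        )
        polar, cart = timing_measures_invariant(traj, default_config)
        assert polar.timing_window in (0.0, n * 1.0)
        assert polar.timing_window == cart.timing_window
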