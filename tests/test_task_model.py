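"""Physics of a single throw: lever kinematics, closed-form flight, scoring."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skittles.config import TaskConfig
from skittles.task_model import (
    BallLaunch,
    ReleaseState,
    ball_position,
    ball_velocity,
    cartesian_to_polar_exec,
    classify_error,
    estimate_angular_velocity,
    estimate_velocity_series,
    launch_from_cartesian,
    launch_to_flight_params,
    lever_state_to_launch,
    polar_to_cartesian_exec,
    score_states,
    score_throw,
)

from conftest import oracle_score, ols_slope


class TestLeverKinematics:
    def test_vertical_lever_position(self, default_config):
        la = lever_state_to_launch(ReleaseState(90.0, 0.0), default_config)
        assert la.position == pytest.approx((0.0, -110.0), abs=1e-12)
        assert la.velocity == pytest.approx((0.0, 0.0))

    def test_horizontal_lever_position(self, default_config):
        la = lever_state_to_launch(ReleaseState(0.0, 0.0), default_config)
        assert la.position == pytest.approx((40.0, -150.0), abs=1e-12)

    def test_speed_is_length_times_angular_rate(self, default_config):
        # 1 rad/s -> speed L = 40 cm/s at any angle; cross-check against a
        # finite difference of the hand position over theta(t)
        thd = math.degrees(1.0)
        for ang in (0.0, 33.0, 90.0, 141.0):
            la = lever_state_to_launch(ReleaseState(ang, thd), default_config)
            assert math.hypot(*la.velocity) == pytest.approx(40.0, rel=1e-12)
            h = 1e-6
            p1 = lever_state_to_launch(ReleaseState(ang + math.degrees(h), 0.0), default_config)
            fd = (np.array(p1.position) - np.array(la.position)) / h
            assert np.allclose(fd, la.velocity, atol=1e-3)


class TestFlightParams:
    def test_zero_axis_is_degenerate(self, default_config):
        fp = launch_to_flight_params(BallLaunch((0.0, 10.0), (0.0, 0.0)), default_config)
        assert fp.ax == 0.0 and fp.phix == 0.0

    def test_release_at_turning_point_undamped(self):
        cfg = TaskConfig(target_center=(0.0, 80.0), tau=math.inf)
        fp = launch_to_flight_params(BallLaunch((10.0, 0.0), (0.0, 0.0)), cfg)
        assert fp.ax == pytest.approx(10.0)
        assert fp.phix == pytest.approx(math.pi / 2)

    def test_roundtrip_example(self):
        cfg = TaskConfig(target_center=(0.0, 80.0), omega=6.0, tau=10.0)
        la = BallLaunch((10.0, -3.0), (50.0, 7.0))
        fp = launch_to_flight_params(la, cfg)
        assert ball_position(fp, 0.0) == pytest.approx(la.position, rel=1e-9)
        assert ball_velocity(fp, 0.0) == pytest.approx(la.velocity, rel=1e-9)
        # analytic derivative agrees with a numerical one
        h = 1e-7
        num = (ball_position(fp, h) - ball_position(fp, 0.0)) / h
        assert np.allclose(num, la.velocity, atol=1e-4)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        angle=st.floats(-180.0, 180.0),
        vel=st.floats(-1000.0, 1000.0),
        omega=st.floats(2.0, 15.0),
        tau=st.floats(0.5, 50.0),
    )
    def test_roundtrip_property(self, angle, vel, omega, tau):
        cfg = TaskConfig(target_center=(0.0, 80.0), omega=omega, tau=tau)
        la = lever_state_to_launch(ReleaseState(angle, vel), cfg)
        fp = launch_to_flight_params(la, cfg)
        scale = max(1.0, max(abs(v) for v in la.velocity))
        assert np.allclose(ball_position(fp, 0.0), la.position, rtol=0, atol=1e-9 * 160)
        assert np.allclose(ball_velocity(fp, 0.0), la.velocity, rtol=0, atol=1e-9 * scale)
        assert -math.pi < fp.phix <= math.pi and -math.pi < fp.phiy <= math.pi
        assert fp.ax >= 0 and fp.ay >= 0


class TestBallPosition:
    def test_zero_amplitude_stays_at_origin(self, default_config):
        fp = launch_to_flight_params(BallLaunch((0.0, 0.0), (0.0, 0.0)), default_config)
        assert np.allclose(ball_position(fp, np.linspace(0, 1, 11)), 0.0)

    def test_undamped_antipodal_passage(self):
        # sin(phi + pi) = -sin(phi): half a period later the ball is at the
        # exact antipode, for any release velocity
        cfg = TaskConfig(target_center=(0.0, 80.0), tau=math.inf)
        for vel in (11.0, 300.0, 888.0):
            la = lever_state_to_launch(ReleaseState(107.0, vel), cfg)
            fp = launch_to_flight_params(la, cfg)
            t0 = 0.123
            p = ball_position(fp, t0)
            q = ball_position(fp, t0 + math.pi / cfg.omega)
            assert np.allclose(q, -p, atol=1e-9)

    def test_undamped_closed_orbit(self):
        cfg = TaskConfig(target_center=(0.0, 80.0), tau=math.inf)
        la = lever_state_to_launch(ReleaseState(70.0, 400.0), cfg)
        fp = launch_to_flight_params(la, cfg)
        assert np.allclose(
            ball_position(fp, 2 * math.pi / cfg.omega), ball_position(fp, 0.0), atol=1e-9
        )

    def test_damped_amplitude_decay(self):
        cfg = TaskConfig(target_center=(0.0, 80.0), tau=2.0)
        la = lever_state_to_launch(ReleaseState(90.0, 500.0), cfg)
        fp = launch_to_flight_params(la, cfg)
        T = 2 * math.pi / cfg.omega
        p0 = ball_position(fp, 0.2)
        p1 = ball_position(fp, 0.2 + T)  # same phase, one period later
        assert np.allclose(p1, p0 * math.exp(-T / cfg.tau), rtol=1e-9)


class TestScoreThrow:
    def test_constructed_zero_error(self, default_config):
        state = ReleaseState(75.0, 420.0)
        la = lever_state_to_launch(state, default_config)
        fp = launch_to_flight_params(la, default_config)
        target = ball_position(fp, 0.31)
        assert np.hypot(*(target)) > default_config.contact_radius + 5
        cfg = default_config.replace(target_center=(float(target[0]), float(target[1])))
        res = score_throw(state, cfg)
        assert res.error < 1e-6
        assert res.category == "hit"
        assert res.time_of_closest_approach == pytest.approx(0.31, abs=1e-4)

    def test_antipodal_target_no_post(self):
        cfg = TaskConfig(target_center=(0.0, 80.0), tau=math.inf, post_radius=0.0)
        la = lever_state_to_launch(ReleaseState(98.0, 0.0), cfg)
        anti = (-la.position[0], -la.position[1])
        cfg = cfg.replace(target_center=anti)
        for vel in (15.0, 230.0, 990.0):
            assert score_throw(ReleaseState(98.0, vel), cfg).error < 1e-6

    def test_near_category_band(self, default_config):
        # place the target 1.5 cm off a point on the flight path
        state = ReleaseState(80.0, 350.0)
        la = lever_state_to_launch(state, default_config)
        fp = launch_to_flight_params(la, default_config)
        p = ball_position(fp, 0.25)
        d = p / np.hypot(*p)
        cfg = default_config.replace(target_center=(float(p[0] + 1.5 * d[0]), float(p[1] + 1.5 * d[1])))
        res = score_throw(state, cfg)
        assert res.error <= 1.5 + 1e-6
        if 1.1 <= res.error < 2.5 and not res.post_hit:
            assert res.category == "near"

    def test_matches_dense_oracle(self, default_config, rng):
        angles = rng.uniform(0.0, 180.0, 60)
        vels = rng.uniform(-1000.0, 1000.0, 60)
        arr = score_states(angles, vels, default_config)
        for i in range(angles.size):
            expected, post = oracle_score(angles[i], vels[i], default_config)
            assert arr.error[i] == pytest.approx(expected, abs=0.01)
            assert bool(arr.post_hit[i]) == post

    def test_single_vs_batch_bit_identical(self, default_config, rng):
        angles = rng.uniform(0.0, 180.0, 25)
        vels = rng.uniform(-800.0, 800.0, 25)
        batch = score_states(angles, vels, default_config)
        for i in (0, 7, 24):
            single = score_throw(ReleaseState(angles[i], vels[i]), default_config)
            assert single.error == batch.error[i]

    def test_rejects_non_finite_state(self, default_config):
        with pytest.raises(ValueError):
            score_throw(ReleaseState(float("nan"), 100.0), default_config)

    def test_release_inside_post_is_invalid(self):
        # lever circle point inside an oversized post: immediate contact
        cfg = TaskConfig(target_center=(0.0, 80.0), post_radius=130.0, miss_threshold=2.5)
        res = score_throw(ReleaseState(90.0, 300.0), cfg)
        assert res.post_hit and res.category == "invalid"


class TestAngularVelocityEstimate:
    def test_constant_angle_gives_zero(self):
        assert estimate_angular_velocity(np.full(40, 33.0), 30, 1000.0) == pytest.approx(0.0)

    def test_exact_linear_ramp(self):
        t = np.arange(100) / 1000.0
        assert estimate_angular_velocity(100.0 * t, 60, 1000.0) == pytest.approx(100.0, rel=1e-9)

    def test_quadratic_matches_ols_oracle(self):
        t = np.arange(0, 501) / 1000.0
        angles = 50.0 * t**2
        got = estimate_angular_velocity(angles, 500, 1000.0)
        expected = ols_slope(angles[480:500], t[480:500])
        assert got == pytest.approx(expected, rel=1e-9)

    def test_insufficient_history_rejected(self):
        with pytest.raises(ValueError):
            estimate_angular_velocity(np.zeros(50), 19, 1000.0)

    def test_series_matches_pointwise_estimates(self):
        rng = np.random.default_rng(7)
        angles = np.cumsum(rng.normal(0, 0.5, 120))
        series = estimate_velocity_series(angles, 1000.0)
        for i in (20, 47, 119):
            assert series[i] == estimate_angular_velocity(angles, i, 1000.0)
        assert np.all(series[:20] == series[20])  # back-filled head


class TestCoordinateFrames:
    def test_forward_map_at_zero_angle(self, default_config):
        v = polar_to_cartesian_exec(ReleaseState(0.0, 100.0), default_config)
        thd = math.radians(100.0)
        assert v == pytest.approx((0.0, 40.0 * thd), abs=1e-12)
        back = cartesian_to_polar_exec(v, default_config)
        assert back.angle == pytest.approx(0.0, abs=1e-9)
        assert back.angular_velocity == pytest.approx(100.0, rel=1e-9)

    def test_round_trip_identity(self, default_config, rng):
        sgn = default_config.direction_sign
        for _ in range(50):
            st_ = ReleaseState(rng.uniform(-180, 180), sgn * rng.uniform(1.0, 1000.0))
            v = polar_to_cartesian_exec(st_, default_config)
            back = cartesian_to_polar_exec(v, default_config)
            assert math.cos(math.radians(back.angle)) == pytest.approx(
                math.cos(math.radians(st_.angle)), abs=1e-9
            )
            assert math.sin(math.radians(back.angle)) == pytest.approx(
                math.sin(math.radians(st_.angle)), abs=1e-9
            )
            assert back.angular_velocity == pytest.approx(st_.angular_velocity, rel=1e-9)

    def test_same_physical_launch_same_error(self, default_config, rng):
        sgn = default_config.direction_sign
        for _ in range(50):
            st_ = ReleaseState(rng.uniform(0, 180), sgn * rng.uniform(10.0, 1000.0))
            v = polar_to_cartesian_exec(st_, default_config)
            la1 = lever_state_to_launch(st_, default_config)
            la2 = launch_from_cartesian(v, default_config)
            assert np.allclose(la1.position, la2.position, atol=1e-9)
            r1 = score_throw(st_, default_config)
            r2 = score_throw(cartesian_to_polar_exec(v, default_config), default_config)
            assert r1.error == pytest.approx(r2.error, abs=1e-9)
            assert r1.category == r2.category

    def test_zero_vector_rejected(self, default_config):
        with pytest.raises(ValueError):
            cartesian_to_polar_exec((0.0, 0.0), default_config)


def test_classify_error_boundaries(default_config):
    errors = np.array([0.5, 1.1, 2.0, 2.5, 39.0, 41.0, 0.5])
    post = np.array([False, False, False, False, False, False, True])
    cats = classify_error(errors, post, default_config)
    assert list(cats) == [0, 1, 1, 2, 2, 3, 3]
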