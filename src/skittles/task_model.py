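"""Physics and geometry of a single throw.

The thrower rotates a lever arm (length ``L``, pivot below the workspace
origin) and releases a virtual ball.  At release the ball detaches from the
lever with the hand's instantaneous position and tangential velocity, and
from then on moves as if attached to two orthogonal massless springs with
rest position at the workspace origin.  With natural frequency ``omega`` and
damping time constant ``tau`` the flight has the closed form

    x(t) = Ax * sin(omega*t + phi_x) * exp(-t/tau)
    y(t) = Ay * sin(omega*t + phi_y) * exp(-t/tau)

i.e. a damped ellipse centred on the origin.  The amplitudes and phases are
recovered per axis from the launch position and velocity.  A throw is scored
by the minimum distance between the ball path and the target centre over one
full oscillation period, truncating the path at the first contact with the
central post.

The internal scorer is vectorised over batches of release states; the
per-sample arithmetic is identical regardless of the batch size, so scoring
a single throw and scoring the same state inside a grid or an arm trajectory
give bit-identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from ._scoring import score_launches
from .config import TaskConfig

__all__ = [
    "ReleaseState",
    "BallLaunch",
    "FlightParams",
    "ThrowResult",
    "CATEGORY_NAMES",
    "lever_state_to_launch",
    "launch_to_flight_params",
    "ball_position",
    "ball_velocity",
    "score_throw",
    "score_states",
    "classify_error",
    "estimate_angular_velocity",
    "estimate_velocity_series",
    "polar_to_cartesian_exec",
    "cartesian_to_polar_exec",
    "launch_from_cartesian",
]

# throw categories, in the order used for integer grid exports
CATEGORY_HIT, CATEGORY_NEAR, CATEGORY_MISS, CATEGORY_INVALID = 0, 1, 2, 3
CATEGORY_NAMES = {
    CATEGORY_HIT: "hit",
    CATEGORY_NEAR: "near",
    CATEGORY_MISS: "miss",
    CATEGORY_INVALID: "invalid",
}

#: number of trailing samples used for the angular-velocity estimate
VELOCITY_FIT_SAMPLES = 20
# zero-mean regressor for the trailing linear fit and its sum of squares
_SLOPE_W = np.arange(VELOCITY_FIT_SAMPLES, dtype=float) - (VELOCITY_FIT_SAMPLES - 1) / 2.0
_SLOPE_SS = float(np.sum(_SLOPE_W**2))  # = 665 for a 20-sample window

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ReleaseState:
    """Execution variables of one throw: lever angle (deg) and angular
    velocity (deg/s, signed, counterclockwise positive)."""

    angle: float
    angular_velocity: float


@dataclass(frozen=True)
class BallLaunch:
    """Cartesian launch state of the ball: position and velocity (cm, cm/s)."""

    position: tuple[float, float]
    velocity: tuple[float, float]


@dataclass(frozen=True)
class FlightParams:
    """Closed-form flight coefficients per axis: amplitudes (cm), phases
    (rad, in (-pi, pi]), plus the task's omega (rad/s) and tau (s)."""

    ax: float
    ay: float
    phix: float
    phiy: float
    omega: float
    tau: float


@dataclass(frozen=True)
class ThrowResult:
    """Outcome of one throw.

    ``error`` is the minimum centre-to-centre distance between ball path and
    target (cm), ``time_of_closest_approach`` the flight time at which it is
    attained, ``post_hit`` whether the ball touched the post, and
    ``category`` one of ``hit``/``near``/``miss``/``invalid``.
    """

    error: float
    post_hit: bool
    time_of_closest_approach: float
    category: str


class ScoreArrays(NamedTuple):
    """Vectorised scoring output for a batch of release states."""

    error: np.ndarray
    post_hit: np.ndarray
    time_of_closest_approach: np.ndarray
    category: np.ndarray  # integer codes, see CATEGORY_NAMES


# ---------------------------------------------------------------------------
# lever kinematics and execution-variable coordinate frames


def lever_state_to_launch(state: ReleaseState, config: TaskConfig) -> BallLaunch:
    """Map a release state to the Cartesian launch state of the ball.

    The hand (and ball) sits at ``pivot + L*(cos(theta), sin(theta))`` and
    moves tangentially with speed ``L*|theta_dot|``; theta is measured from
    the workspace +x axis, counterclockwise positive.
    """
    th = math.radians(state.angle)
    thd = math.radians(state.angular_velocity)
    L = config.lever_length
    px, py = config.lever_pivot
    pos = (px + L * math.cos(th), py + L * math.sin(th))
    vel = (-L * thd * math.sin(th), L * thd * math.cos(th))
    return BallLaunch(position=pos, velocity=vel)


def polar_to_cartesian_exec(state: ReleaseState, config: TaskConfig) -> np.ndarray:
    """Cartesian execution variables: the release velocity vector (cm/s)."""
    return np.asarray(lever_state_to_launch(state, config).velocity)


def cartesian_to_polar_exec(v: Sequence[float], config: TaskConfig) -> ReleaseState:
    """Invert :func:`polar_to_cartesian_exec`.

    The tangential velocity alone leaves a two-fold ambiguity in the lever
    angle; the task's ``throw_direction`` resolves it.  The zero vector is
    rejected (its release angle is undefined).
    """
    vx, vy = float(v[0]), float(v[1])
    speed = math.hypot(vx, vy)
    if speed == 0.0:
        raise ValueError("cannot invert the zero velocity vector")
    sgn = config.direction_sign
    ux, uy = vx / speed, vy / speed
    # v = L*thd*(-sin th, cos th) with sign(thd) = sgn
    theta = math.atan2(-sgn * ux, sgn * uy)
    thd = sgn * speed / config.lever_length
    return ReleaseState(angle=math.degrees(theta), angular_velocity=math.degrees(thd))


def launch_from_cartesian(v: Sequence[float], config: TaskConfig) -> BallLaunch:
    """Ball launch reconstructed directly from Cartesian execution variables.

    The release position is the point on the lever circle whose tangent (in
    the task's throw direction) is parallel to ``v``.
    """
    vx, vy = float(v[0]), float(v[1])
    speed = math.hypot(vx, vy)
    if speed == 0.0:
        raise ValueError("cannot place the zero velocity vector on the lever circle")
    sgn = config.direction_sign
    ux, uy = vx / speed, vy / speed
    # radial unit vector: (cos th, sin th) = sgn * (uy, -ux)
    rx, ry = sgn * uy, -sgn * ux
    px, py = config.lever_pivot
    L = config.lever_length
    return BallLaunch(position=(px + L * rx, py + L * ry), velocity=(vx, vy))


# ---------------------------------------------------------------------------
# closed-form flight


def launch_to_flight_params(launch: BallLaunch, config: TaskConfig) -> FlightParams:
    """Recover per-axis amplitude and phase from the launch state.

    Writing x(t) = exp(-t/tau) * (x0*cos(omega t) + kx*sin(omega t)) with
    kx = (vx0 + x0/tau)/omega gives Ax = hypot(x0, kx), phi_x = atan2(x0, kx).
    A degenerate axis (x0 = 0 and vx0 + x0/tau = 0) maps to (A, phi) = (0, 0).
    """

    def axis(x0: float, v0: float) -> tuple[float, float]:
        k = (v0 + x0 / config.tau) / config.omega
        a = math.hypot(x0, k)
        if a == 0.0:
            return 0.0, 0.0
        phi = math.atan2(x0, k)
        if phi <= -math.pi:  # normalise to (-pi, pi]
            phi = math.pi
        return a, phi

    ax, phix = axis(launch.position[0], launch.velocity[0])
    ay, phiy = axis(launch.position[1], launch.velocity[1])
    return FlightParams(ax=ax, ay=ay, phix=phix, phiy=phiy, omega=config.omega, tau=config.tau)


def ball_position(params: FlightParams, t):
    """Ball position at flight time ``t`` (scalar or array); shape (2,) or (2, n)."""
    t = np.asarray(t, dtype=float)
    env = np.exp(-t / params.tau)
    x = params.ax * np.sin(params.omega * t + params.phix) * env
    y = params.ay * np.sin(params.omega * t + params.phiy) * env
    return np.stack([x, y])


def ball_velocity(params: FlightParams, t):
    """Analytic time derivative of :func:`ball_position`."""
    t = np.asarray(t, dtype=float)
    env = np.exp(-t / params.tau)
    w = params.omega
    x = params.ax * env * (w * np.cos(w * t + params.phix) - np.sin(w * t + params.phix) / params.tau)
    y = params.ay * env * (w * np.cos(w * t + params.phiy) - np.sin(w * t + params.phiy) / params.tau)
    return np.stack([x, y])


# ---------------------------------------------------------------------------
# angular-velocity estimation (trailing 20-sample linear fit)


def _trailing_slope(window: np.ndarray, dt: float) -> float:
    # fixed-order accumulation so scalar and vectorised paths round identically
    acc = 0.0
    for k in range(VELOCITY_FIT_SAMPLES):
        acc += _SLOPE_W[k] * window[k]
    return acc / _SLOPE_SS / dt


def estimate_angular_velocity(angles: Sequence[float], at_index: int, sample_rate: float) -> float:
    """OLS slope (deg/s) over the 20 angle samples strictly before ``at_index``."""
    angles = np.asarray(angles, dtype=float)
    if at_index < VELOCITY_FIT_SAMPLES:
        raise ValueError(
            f"need at least {VELOCITY_FIT_SAMPLES} samples before index {at_index} "
            "to estimate angular velocity"
        )
    window = angles[at_index - VELOCITY_FIT_SAMPLES : at_index]
    return _trailing_slope(window, 1.0 / sample_rate)


def estimate_velocity_series(angles: Sequence[float], sample_rate: float) -> np.ndarray:
    """Per-sample angular velocity using the same trailing 20-sample fit.

    Samples with fewer than 20 predecessors are back-filled with the first
    estimable value so the series aligns index-for-index with the angles.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n < VELOCITY_FIT_SAMPLES + 1:
        raise ValueError("trajectory too short for velocity estimation")
    dt = 1.0 / sample_rate
    m = n - VELOCITY_FIT_SAMPLES  # estimates for indices 20..n-1
    acc = np.zeros(m)
    for k in range(VELOCITY_FIT_SAMPLES):
        acc += _SLOPE_W[k] * angles[k : k + m]
    est = acc / _SLOPE_SS / dt
    out = np.empty(n)
    out[VELOCITY_FIT_SAMPLES:] = est
    out[:VELOCITY_FIT_SAMPLES] = est[0]
    return out


# ---------------------------------------------------------------------------
# scoring


def classify_error(error, post_hit, config: TaskConfig) -> np.ndarray:
    """Integer throw category from error (cm) and post-hit flag.

    hit: error < success_threshold and no post hit; near: error in
    [success, miss) and no post hit; invalid: post hit or error beyond
    max_display_error; miss otherwise.
    """
    error = np.asarray(error, dtype=float)
    post_hit = np.asarray(post_hit, dtype=bool)
    cat = np.full(error.shape, CATEGORY_MISS, dtype=np.int8)
    cat[error < config.miss_threshold] = CATEGORY_NEAR
    cat[error < config.success_threshold] = CATEGORY_HIT
    cat[error > config.max_display_error] = CATEGORY_INVALID
    cat[post_hit] = CATEGORY_INVALID
    return cat


def _score_launch_arrays(x0, y0, vx0, vy0, config: TaskConfig) -> ScoreArrays:
    err, post_hit, tcl, _ = score_launches(x0, y0, vx0, vy0, config)
    category = classify_error(err, post_hit, config)
    return ScoreArrays(error=err, post_hit=post_hit, time_of_closest_approach=tcl, category=category)


def score_states(angles_deg, velocities_deg_s, config: TaskConfig, chunk: int = 4096) -> ScoreArrays:
    """Score a batch of release states given as parallel arrays (deg, deg/s)."""
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    vels = np.atleast_1d(np.asarray(velocities_deg_s, dtype=float))
    if angles.shape != vels.shape:
        raise ValueError("angle and velocity arrays must have the same shape")
    if not (np.isfinite(angles).all() and np.isfinite(vels).all()):
        raise ValueError("release states must be finite")
    th = np.radians(angles)
    thd = np.radians(vels)
    L = config.lever_length
    px, py = config.lever_pivot
    x0 = px + L * np.cos(th)
    y0 = py + L * np.sin(th)
    vx0 = -L * thd * np.sin(th)
    vy0 = L * thd * np.cos(th)
    return _score_launch_arrays(x0, y0, vx0, vy0, config)


def score_throw(state: ReleaseState, config: TaskConfig) -> ThrowResult:
    """Simulate and score a single throw from its release state."""
    arr = score_states([state.angle], [state.angular_velocity], config)
    return ThrowResult(
        error=float(arr.error[0]),
        post_hit=bool(arr.post_hit[0]),
        time_of_closest_approach=float(arr.time_of_closest_approach[0]),
        category=CATEGORY_NAMES[int(arr.category[0])],
    )
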