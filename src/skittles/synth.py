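"""Synthetic arm-trajectory generation.

No generative model of human throwing trajectories exists for this task, so
the package ships a deliberately simple stand-in that has the statistical
structure the analysis assumes: a minimum-jerk single-joint rotation
(the canonical smooth point-to-point profile) sampled at the task rate,
with trial-to-trial Gaussian noise on amplitude and duration, and Gaussian
jitter on the release time emulating intrinsic neuromotor timing noise.
Sessions follow the experimental protocol of 240 throws per day in 4 blocks.

:func:`calibrate_strategy_to_manifold` searches for a strategy (start/end
angle, movement time) whose noiseless trajectory overlaps the solution
manifold long enough to reach a requested timing window — the geometric
"molding" of the trajectory to the manifold that practice produces.  On an
I-shape geometry no such strategy exists short of infinite acceleration, and
the search reports the single-crossing floor instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .config import TaskConfig
from .task_model import VELOCITY_FIT_SAMPLES
from .timing import ArmTrajectory, error_trajectory
from .solution_space import SolutionSpaceGrid, evaluate_grid, extract_manifold

__all__ = [
    "StrategyParams",
    "NoiseModel",
    "LearnerSchedule",
    "CalibrationResult",
    "generate_arm_trajectory",
    "generate_session",
    "calibrate_strategy_to_manifold",
    "strategy_through_state",
    "PracticeRamp",
    "design_practice_ramp",
    "learning_schedule",
    "jitter_schedule_ms",
    "throw_seed",
]

#: minimum-jerk position profile h(s) on s in [0, 1]
def _minjerk(s: np.ndarray) -> np.ndarray:
    return 10.0 * s**3 - 15.0 * s**4 + 6.0 * s**5


#: peak of the min-jerk speed profile 30*s^2*(1-s)^2, attained at s = 1/2
MINJERK_PEAK_SPEED = 1.875


@dataclass(frozen=True)
class StrategyParams:
    """One throwing strategy: where the sweep starts and ends (deg), how
    long it takes (s), when the release is planned (fraction of the
    movement time, in (0, 1)), and how much follow-through is simulated
    after the movement (fraction of the movement time)."""

    start_angle: float
    end_angle: float
    movement_time: float
    planned_release_fraction: float = 0.6
    follow_through_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not self.movement_time > 0:
            raise ValueError("movement_time must be > 0")
        if not 0.0 < self.planned_release_fraction < 1.0:
            raise ValueError("planned_release_fraction must lie in (0, 1)")
        if self.follow_through_fraction < 0:
            raise ValueError("follow_through_fraction must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Trial-to-trial noise: release-time jitter (ms), amplitude noise
    (deg), duration noise (ms); all Gaussian, all SDs >= 0."""

    release_jitter_sd: float = 10.0
    amplitude_sd: float = 1.5
    duration_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.release_jitter_sd, self.amplitude_sd, self.duration_sd) < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class LearnerSchedule:
    """Per-day strategy and noise for one simulated learner."""

    strategies: tuple[StrategyParams, ...]
    noise: tuple[NoiseModel, ...]
    throws_per_day: int = 240
    blocks: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategies", tuple(self.strategies))
        object.__setattr__(self, "noise", tuple(self.noise))
        if len(self.strategies) < 1 or len(self.strategies) != len(self.noise):
            raise ValueError("need one StrategyParams and one NoiseModel per day")
        if self.throws_per_day % self.blocks != 0:
            raise ValueError("throws_per_day must be divisible by blocks")

    @property
    def days(self) -> int:
        return len(self.strategies)


def generate_arm_trajectory(
    sp: StrategyParams, nm: NoiseModel, config: TaskConfig
) -> ArmTrajectory:
    """One noisy minimum-jerk trajectory with its release sample.

    The angular profile is theta(s) = start + dtheta*(10 s^3 - 15 s^4 + 6 s^5)
    over the jittered movement duration, held at the end angle through the
    follow-through span.  The release sample is the planned release time
    plus Gaussian jitter, truncated to the valid sample range.  Fully
    deterministic given the noise model's seed.
    """
    if sp.end_angle == sp.start_angle:
        raise ValueError("degenerate strategy: start and end angle coincide")
    rng = np.random.default_rng(nm.seed)
    dur_jit = rng.normal(0.0, nm.duration_sd / 1000.0)
    amp_jit = rng.normal(0.0, nm.amplitude_sd)
    rel_jit = rng.normal(0.0, nm.release_jitter_sd / 1000.0)

    T = max(sp.movement_time + dur_jit, 0.05)
    dtheta = (sp.end_angle - sp.start_angle) + amp_jit
    sr = config.sample_rate
    span = T * (1.0 + sp.follow_through_fraction)
    n = int(round(span * sr)) + 1
    t = np.arange(n) / sr
    s = np.clip(t / T, 0.0, 1.0)
    angle = sp.start_angle + dtheta * _minjerk(s)

    release_t = sp.planned_release_fraction * T + rel_jit
    release_index = int(round(release_t * sr))
    release_index = min(max(release_index, VELOCITY_FIT_SAMPLES), n - 1)
    return ArmTrajectory(
        time=t, angle=angle, release_index=release_index, sample_rate=sr
    )


def throw_seed(base_seed: int, day: int, throw: int) -> int:
    """Deterministic per-throw sub-seed via counter-based seed derivation."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(day, throw))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def generate_session(
    sched: LearnerSchedule, day: int, config: TaskConfig
) -> list[ArmTrajectory]:
    """All trajectories of one practice day (1-based), one per throw.

    Per-throw noise seeds are derived deterministically from the day's base
    seed and the (day, throw) counter, so distinct throws always receive
    distinct noise draws and the whole session is reproducible.
    """
    if not 1 <= day <= sched.days:
        raise ValueError(f"day must be in 1..{sched.days}")
    sp = sched.strategies[day - 1]
    nm = sched.noise[day - 1]
    out = []
    for throw in range(sched.throws_per_day):
        nmt = replace(nm, seed=throw_seed(nm.seed, day, throw))
        out.append(generate_arm_trajectory(sp, nmt, config))
    return out


# ---------------------------------------------------------------------------
# strategy calibration


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the manifold-alignment search."""

    params: StrategyParams
    achieved_window_ms: float
    achieved: bool
    release_angle: float
    release_velocity: float  # signed, deg/s
    release_fraction: float  # min-jerk phase of the release


def strategy_through_state(
    theta: float,
    theta_dot: float,
    release_fraction: float,
    movement_time: float,
    follow_through_fraction: float = 0.25,
) -> StrategyParams:
    """Build a minimum-jerk strategy that passes through the release state
    (theta deg, theta_dot deg/s) at min-jerk phase ``release_fraction``.

    The sweep amplitude follows from the min-jerk speed profile
    theta_dot = 30*(dtheta/T)*s^2*(1-s)^2, so for a fixed release state and
    phase, varying the movement time changes the sweep's angular extent and
    its acceleration (alignment with the manifold) but not the release
    velocity itself.
    """
    s = release_fraction
    shape = 30.0 * s * s * (1.0 - s) * (1.0 - s)
    if shape <= 0:
        raise ValueError("release_fraction must lie strictly inside (0, 1)")
    dtheta = theta_dot * movement_time / shape
    start = theta - dtheta * float(_minjerk(np.asarray(s)))
    return StrategyParams(
        start_angle=start,
        end_angle=start + dtheta,
        movement_time=movement_time,
        planned_release_fraction=s,
        follow_through_fraction=follow_through_fraction,
    )


def _noiseless(sp: StrategyParams, config: TaskConfig) -> ArmTrajectory:
    return generate_arm_trajectory(sp, NoiseModel(0.0, 0.0, 0.0, seed=0), config)


def _window_at_ideal(sp: StrategyParams, config: TaskConfig) -> tuple[float, StrategyParams]:
    """Timing window (ms) of the noiseless trajectory released at its ideal
    sample; returns the strategy with the release fraction moved there.

    The ideal sample is the error minimum of the sub-threshold run nearest
    the planned crossing (the manifold crossing the strategy was built
    around), or the global error minimum when the trajectory never crosses
    the manifold.  Anchoring on the planned crossing keeps the measure
    continuous as the movement time is varied, instead of hopping between
    disjoint solution branches.
    """
    traj = _noiseless(sp, config)
    et = error_trajectory(traj, config)
    planned = sp.planned_release_fraction * sp.movement_time * config.sample_rate
    runs = et.subthreshold_intervals
    if runs:
        mids = [0.5 * (lo + hi) for lo, hi in runs]
        k = int(np.argmin([abs(m - planned) for m in mids]))
        lo, hi = runs[k]
        ideal = int(lo + np.argmin(et.error[lo : hi + 1]))
        window = (hi - lo + 1) * 1000.0 / config.sample_rate
    else:
        ideal = int(np.argmin(et.error))
        window = 0.0
    frac = (ideal / config.sample_rate) / sp.movement_time
    if not 0.02 <= frac <= 0.98:
        # ideal release falls outside the movement proper; not a usable strategy
        return 0.0, sp
    sp2 = replace(sp, planned_release_fraction=frac)
    traj2 = generate_arm_trajectory(sp2, NoiseModel(0.0, 0.0, 0.0, seed=0), config)
    if traj2.release_index != ideal:
        return 0.0, sp2
    return window, sp2


def calibrate_strategy_to_manifold(
    config: TaskConfig,
    target_window_ms: float,
    min_release_speed: float = 200.0,
    max_release_speed: float = 1000.0,
    grid: SolutionSpaceGrid | None = None,
    movement_times: tuple[float, ...] = (0.25, 0.35, 0.45, 0.6, 0.8),
    release_fractions: tuple[float, ...] = (0.45, 0.55, 0.65),
) -> CalibrationResult:
    """Search for a strategy whose noiseless timing window reaches the target.

    Candidate release states are drawn from the solution manifold (restricted
    to a realistic band of release speeds); for each, minimum-jerk sweeps
    through that state are tried over a grid of movement times and release
    phases, and the best achieved window is kept.  The search stops early
    once the target is met.  An empty manifold raises ``ValueError``; a
    geometry on which the target is unreachable (the I-shape case) returns
    its best floor with ``achieved=False``.
    """
    if grid is None:
        grid = evaluate_grid(
            config,
            velocity_range=(min_release_speed, max_release_speed),
            resolution=(96, 96),
        )
    slices = [s for s in extract_manifold(grid) if s.velocity_intervals]
    if not slices:
        raise ValueError("solution manifold is empty over the searched ranges")

    # candidate release states: interval edges and midpoints, favouring low
    # speeds (slower crossings dwell longer near the manifold)
    cands: list[tuple[float, float]] = []
    for s in slices[:: max(1, len(slices) // 12)]:
        for lo, hi in s.velocity_intervals:
            lo = max(lo, min_release_speed)
            cands.append((s.angle, lo))
            cands.append((s.angle, 0.5 * (lo + min(hi, max_release_speed))))
    cands.sort(key=lambda c: c[1])
    cands = cands[:24]

    sgn = config.direction_sign
    best: tuple[float, StrategyParams, float, float, float] | None = None
    for angle, speed in cands:
        for frac in release_fractions:
            for T in movement_times:
                sp = strategy_through_state(angle, sgn * speed, frac, T)
                try:
                    window, sp2 = _window_at_ideal(sp, config)
                except ValueError:
                    continue
                if best is None or window > best[0]:
                    best = (window, sp2, angle, sgn * speed, frac)
                if window >= target_window_ms:
                    return CalibrationResult(
                        params=sp2,
                        achieved_window_ms=window,
                        achieved=True,
                        release_angle=angle,
                        release_velocity=sgn * speed,
                        release_fraction=frac,
                    )
    assert best is not None
    window, sp2, angle, vel, frac = best
    return CalibrationResult(
        params=sp2,
        achieved_window_ms=window,
        achieved=window >= target_window_ms,
        release_angle=angle,
        release_velocity=vel,
        release_fraction=frac,
    )


# ---------------------------------------------------------------------------
# practice schedules


@dataclass(frozen=True)
class PracticeRamp:
    """A practice progression: a fixed release state crossed at min-jerk
    phase ``release_fraction``, with the movement time ramping from
    ``t_naive`` (fast, poorly aligned sweep) to ``t_skilled`` (slow sweep
    molded to the manifold).  ``windows_ms`` records the noiseless timing
    window at the ramp endpoints."""

    release_angle: float
    release_velocity: float  # signed, deg/s
    release_fraction: float
    t_naive: float
    t_skilled: float
    windows_ms: tuple[float, float]


def _ramp_windows(
    angle: float, velocity: float, frac: float, t_grid, config: TaskConfig
) -> list[float]:
    out = []
    for T in t_grid:
        try:
            w, _ = _window_at_ideal(
                strategy_through_state(angle, velocity, frac, T), config
            )
        except ValueError:
            w = -1.0
        out.append(w)
    return out


_MIN_RAMP_POINTS = 6


def _best_segment(windows: list[float], cap: float) -> tuple[float, int, int, int]:
    """Best practice segment of the window-vs-movement-time curve.

    Segments are maximal non-decreasing stretches within the window cap that
    start from a working (nonzero-window) strategy.  Segments long enough to
    cover a multi-day progression smoothly (>= 6 grid points) are preferred,
    ranked by window growth then length; short segments only serve as a
    fallback.  Returns (span, len, i0, i1).
    """
    segs = []
    i = 0
    n = len(windows)
    while i < n:
        if windows[i] <= 0:
            i += 1
            continue
        j = i
        while j + 1 < n and windows[j] <= windows[j + 1] <= cap:
            j += 1
        segs.append((windows[j] - windows[i], j - i + 1, i, j))
        i = j + 1
    if not segs:
        return (-1.0, 1, 0, 0)
    long_enough = [s for s in segs if s[1] >= _MIN_RAMP_POINTS]
    pool = long_enough if long_enough else segs
    return max(pool, key=lambda s: (s[0], s[1]))


def design_practice_ramp(
    config: TaskConfig,
    min_release_speed: float = 200.0,
    max_release_speed: float = 1000.0,
    t_grid: tuple[float, ...] = (
        0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6, 0.65, 0.7,
    ),
    window_cap_ms: float = 60.0,
    grid: SolutionSpaceGrid | None = None,
) -> PracticeRamp:
    """Choose the release state and movement-time ramp for a practice cohort.

    Candidate release states are drawn from the solution manifold; for each
    (state, release phase) the noiseless timing window is scanned over the
    movement-time grid, and the candidate with the longest, largest-span
    non-decreasing window segment wins.  Windows are capped at
    ``window_cap_ms`` (the tens-of-milliseconds scale of skilled throwing)
    so that degenerate slow sweeps that park inside a shallow manifold do
    not dominate.  On an I-shape geometry every candidate's window is flat,
    so whichever ramp is returned leaves the window unchanged — the
    geometric signature of the control task.
    """
    if grid is None:
        grid = evaluate_grid(
            config,
            velocity_range=(min_release_speed, max_release_speed),
            resolution=(96, 96),
        )
    slices = [s for s in extract_manifold(grid) if s.velocity_intervals]
    if not slices:
        raise ValueError("solution manifold is empty over the searched ranges")
    cands: list[tuple[float, float]] = []
    for s in slices[:: max(1, len(slices) // 8)]:
        for lo, hi in s.velocity_intervals:
            lo = max(lo, min_release_speed)
            cands.append((s.angle, lo))
            cands.append((s.angle, 0.5 * (lo + min(hi, max_release_speed))))
    cands.sort(key=lambda c: c[1])
    cands = cands[:16]

    sgn = config.direction_sign
    best_key = (-1, -2.0, -1)
    best: PracticeRamp | None = None
    for angle, speed in cands:
        for frac in (0.45, 0.55, 0.65):
            ws = _ramp_windows(angle, sgn * speed, frac, t_grid, config)
            span, length, i0, i1 = _best_segment(ws, window_cap_ms)
            if ws[i0] <= 0:
                continue
            key = (1 if length >= _MIN_RAMP_POINTS else 0, span, length)
            if key > best_key:
                best_key = key
                best = PracticeRamp(
                    release_angle=angle,
                    release_velocity=sgn * speed,
                    release_fraction=frac,
                    t_naive=t_grid[i0],
                    t_skilled=t_grid[i1],
                    windows_ms=(ws[i0], ws[i1]),
                )
    assert best is not None
    return best


#: default practice-day release-jitter schedule: a fast early drop onto a
#: plateau, emulating the rapid initial improvement of release timing
def jitter_schedule_ms(
    day: int, start: float = 40.0, floor: float = 18.0, decay_days: float = 0.7
) -> float:
    return floor + (start - floor) * math.exp(-(day - 1) / decay_days)


def learning_schedule(
    config: TaskConfig,
    days: int = 6,
    *,
    ramp: PracticeRamp | None = None,
    alignment: float = 1.0,
    jitter_scale: float = 1.0,
    jitter_start: float = 40.0,
    jitter_floor: float = 18.0,
    amplitude_sd: float = 1.5,
    duration_sd: float = 20.0,
    throws_per_day: int = 240,
    blocks: int = 4,
    seed: int = 0,
) -> LearnerSchedule:
    """Practice schedule for one simulated learner.

    Two processes unfold over the ``days`` of practice: release jitter drops
    quickly onto a plateau (``jitter_start`` to ``jitter_floor`` ms, scaled
    by the subject's ``jitter_scale``), and the movement time ramps from the
    naive to the skilled end of the task's practice ramp in proportion to
    ``alignment * day/days`` — slower, better-aligned sweeps that lengthen
    the timing window without changing the release state.  Each day's
    planned release is placed at the ideal sample of that day's noiseless
    trajectory, so the release jitter alone sets the timing error.
    """
    if ramp is None:
        ramp = design_practice_ramp(config)
    t0, t1 = ramp.t_naive, ramp.t_skilled
    strategies = []
    noise = []
    for day in range(1, days + 1):
        progress = alignment * day / days
        T = t0 + (t1 - t0) * progress
        sp = strategy_through_state(
            ramp.release_angle,
            ramp.release_velocity,
            ramp.release_fraction,
            T,
        )
        _, sp = _window_at_ideal(sp, config)
        strategies.append(sp)
        noise.append(
            NoiseModel(
                release_jitter_sd=jitter_scale
                * jitter_schedule_ms(day, jitter_start, jitter_floor),
                amplitude_sd=amplitude_sd,
                duration_sd=duration_sd,
                seed=throw_seed(seed, day, 1_000_000),
            )
        )
    return LearnerSchedule(
        strategies=tuple(strategies),
        noise=tuple(noise),
        throws_per_day=throws_per_day,
        blocks=blocks,
    )


#: frozen practice ramps for the bundled task variants, validated so that the
#: cohort windows grow smoothly on the alignable geometries and stay at the
#: crossing ceiling on the I-shape control (whose band must be crossed at a
#: clean post-clearing speed; grazing the clearance boundary is excluded as
#: it does not represent the instructed behaviour)
BUNDLED_RAMPS: dict[str, PracticeRamp] = {
    "u_shape": PracticeRamp(92.8, -406.0, 0.65, 0.2, 0.6, (6.0, 50.0)),
    "j_shape": PracticeRamp(92.8, -385.0, 0.45, 0.3, 0.55, (6.0, 59.0)),
    "box_shape": PracticeRamp(152.0, 341.0, 0.45, 0.3, 0.7, (15.0, 59.0)),
    "i_shape": PracticeRamp(117.5, 474.0, 0.55, 0.3, 0.6, (28.0, 29.0)),
}


def practice_ramp_for(config: TaskConfig) -> PracticeRamp:
    """The frozen ramp of a bundled task, or a freshly designed one."""
    if config.name in BUNDLED_RAMPS:
        return BUNDLED_RAMPS[config.name]
    return design_practice_ramp(config)
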