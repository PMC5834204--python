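"""Release-timing measures computed from arm trajectories.

An arm trajectory (lever angle sampled at 1 kHz with a marked release
sample) is converted into an *error trajectory* by treating every sample as
a hypothetical ball release and scoring it.  Two per-throw measures follow:

* **timing error** — time between the actual release and the ideal release
  (the error-trajectory minimum, or the nearest sub-threshold local minimum
  when the trajectory crosses the solution manifold more than once);
* **timing window** — duration of the contiguous sub-threshold segment of
  the error trajectory around the ideal release: the tolerance the
  trajectory affords to release-time noise.

Both measures are functions of the sequence of physical ball launches, so
they are invariant under reparameterising the execution variables (polar
lever state vs Cartesian release velocity); :func:`timing_measures_invariant`
computes them along both routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from ._scoring import score_launches
from .config import TaskConfig
from .task_model import (
    VELOCITY_FIT_SAMPLES,
    CATEGORY_NAMES,
    ReleaseState,
    ScoreArrays,
    ThrowResult,
    classify_error,
    estimate_velocity_series,
    score_states,
)

__all__ = [
    "ArmTrajectory",
    "ErrorTrajectory",
    "TimingMeasures",
    "error_trajectory",
    "timing_error",
    "timing_window",
    "compute_timing_measures",
    "analyze_throw",
    "timing_measures_invariant",
    "REFERENCE_RULES",
]

REFERENCE_RULES = ("nearest_crossing", "global_min", "window_midpoint")


@dataclass
class ArmTrajectory:
    """Uniformly sampled lever-angle time series with a marked release.

    ``angular_velocity`` may be supplied (e.g. from an encoder); when absent
    it is derived per sample with the same trailing 20-sample linear fit
    used for the release state, back-filled over the first 20 samples.
    """

    time: np.ndarray
    angle: np.ndarray
    release_index: int
    angular_velocity: np.ndarray | None = None
    sample_rate: float = field(default=1000.0)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.time.shape != self.angle.shape or self.time.ndim != 1:
            raise ValueError("time and angle must be 1-D arrays of equal length")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=0.0, atol=1e-9):
                raise ValueError("trajectory must be uniformly sampled")
        if not 0 <= self.release_index < self.time.size:
            raise ValueError("release_index out of range")
        if self.angular_velocity is not None:
            self.angular_velocity = np.asarray(self.angular_velocity, dtype=float)
            if self.angular_velocity.shape != self.angle.shape:
                raise ValueError("angular_velocity must match the angle series")

    def __len__(self) -> int:
        return self.time.size

    def velocities(self) -> np.ndarray:
        if self.angular_velocity is not None:
            return self.angular_velocity
        return estimate_velocity_series(self.angle, self.sample_rate)

    def release_state(self) -> ReleaseState:
        vel = self.velocities()
        return ReleaseState(
            angle=float(self.angle[self.release_index]),
            angular_velocity=float(vel[self.release_index]),
        )


@dataclass(frozen=True)
class ErrorTrajectory:
    """Per-sample hypothetical-release error series of one arm trajectory."""

    time: np.ndarray
    error: np.ndarray
    post_hit: np.ndarray
    ideal_index: int
    subthreshold_intervals: list[tuple[int, int]]  # inclusive sample runs
    success_threshold: float = 1.1


@dataclass(frozen=True)
class TimingMeasures:
    """Per-throw timing measures (ms) and the reference rule that produced
    the ideal release time (s)."""

    timing_error: float
    timing_window: float
    ideal_release_time: float
    reference_rule: str


def _subthreshold_runs(error: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    below = error < threshold
    if not below.any():
        return []
    d = np.diff(below.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0])
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(below.size - 1)
    return list(zip(starts, ends))


def _run_minima(error: np.ndarray, runs: list[tuple[int, int]]) -> list[int]:
    # representative local minimum of each sub-threshold run
    return [int(lo + np.argmin(error[lo : hi + 1])) for lo, hi in runs]


def _select_reference(
    error: np.ndarray,
    runs: list[tuple[int, int]],
    release_index: int,
) -> tuple[float, tuple[int, int] | None]:
    """Nearest-crossing reference: the sub-threshold local minimum closest in
    time to the release; falls back to the global minimum when the
    trajectory never crosses the manifold.  Returns (reference index,
    containing run)."""
    if runs:
        minima = _run_minima(error, runs)
        dist = [abs(m - release_index) for m in minima]
        k = int(np.argmin(dist))
        return float(minima[k]), runs[k]
    return float(np.argmin(error)), None


def error_trajectory(traj: ArmTrajectory, config: TaskConfig) -> ErrorTrajectory:
    """Score every sample of an arm trajectory as a hypothetical release.

    Each sample's error equals exactly what :func:`~skittles.task_model.score_throw`
    returns for that (angle, velocity) state, so the value at the release
    sample is the throw's actual performance error.
    """
    et, _ = _error_trajectory_full(traj, config)
    return et


def _error_trajectory_full(
    traj: ArmTrajectory, config: TaskConfig
) -> tuple[ErrorTrajectory, ScoreArrays]:
    if len(traj) < VELOCITY_FIT_SAMPLES + 1:
        raise ValueError("trajectory too short to build an error trajectory")
    vel = traj.velocities()
    arr = score_states(traj.angle, vel, config)
    return _assemble(traj, arr, config), arr


def _assemble(traj: ArmTrajectory, arr: ScoreArrays, config: TaskConfig) -> ErrorTrajectory:
    runs = _subthreshold_runs(arr.error, config.success_threshold)
    ref, _ = _select_reference(arr.error, runs, traj.release_index)
    return ErrorTrajectory(
        time=traj.time,
        error=arr.error,
        post_hit=arr.post_hit,
        ideal_index=int(round(ref)),
        subthreshold_intervals=runs,
        success_threshold=config.success_threshold,
    )


def _sample_period_ms(et: ErrorTrajectory) -> float:
    if et.time.size < 2:
        return 1.0
    return float(et.time[1] - et.time[0]) * 1000.0


def timing_error(
    et: ErrorTrajectory, release_index: int, rule: str = "nearest_crossing"
) -> float:
    """Timing error (ms) of a release against the chosen reference rule.

    ``global_min`` uses the error-trajectory minimum; ``nearest_crossing``
    (default) prefers the sub-threshold local minimum nearest in time to the
    release, falling back to the global minimum; ``window_midpoint`` places
    the reference at the midpoint of the selected sub-threshold segment.
    """
    if rule not in REFERENCE_RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {REFERENCE_RULES}")
    dt_ms = _sample_period_ms(et)
    if rule == "global_min":
        ref = float(np.argmin(et.error))
    else:
        ref, run = _select_reference(et.error, et.subthreshold_intervals, release_index)
        if rule == "window_midpoint" and run is not None:
            ref = 0.5 * (run[0] + run[1])
    return abs(release_index - ref) * dt_ms


def timing_window(et: ErrorTrajectory, release_index: int) -> float:
    """Timing window (ms): duration of the sub-threshold run containing the
    nearest-crossing reference; 0 when the trajectory never dips below the
    success threshold.  The run duration is its sample count times the
    sampling interval, with no sub-sample interpolation."""
    _, run = _select_reference(et.error, et.subthreshold_intervals, release_index)
    if run is None:
        return 0.0
    return (run[1] - run[0] + 1) * _sample_period_ms(et)


def compute_timing_measures(
    et: ErrorTrajectory, release_index: int, rule: str = "nearest_crossing"
) -> TimingMeasures:
    """Bundle timing error and timing window for one throw."""
    dt = _sample_period_ms(et) / 1000.0
    if rule == "global_min":
        ref = float(np.argmin(et.error))
    else:
        ref, run = _select_reference(et.error, et.subthreshold_intervals, release_index)
        if rule == "window_midpoint" and run is not None:
            ref = 0.5 * (run[0] + run[1])
    return TimingMeasures(
        timing_error=timing_error(et, release_index, rule),
        timing_window=timing_window(et, release_index),
        ideal_release_time=ref * dt,
        reference_rule=rule,
    )


def analyze_throw(
    traj: ArmTrajectory, config: TaskConfig, rule: str = "nearest_crossing"
) -> tuple[ThrowResult, TimingMeasures]:
    """Score a recorded throw and compute its timing measures in one pass."""
    et, arr = _error_trajectory_full(traj, config)
    i = traj.release_index
    result = ThrowResult(
        error=float(arr.error[i]),
        post_hit=bool(arr.post_hit[i]),
        time_of_closest_approach=float(arr.time_of_closest_approach[i]),
        category=CATEGORY_NAMES[int(arr.category[i])],
    )
    return result, compute_timing_measures(et, i, rule)


def timing_measures_invariant(
    traj: ArmTrajectory, config: TaskConfig, rule: str = "nearest_crossing"
) -> tuple[TimingMeasures, TimingMeasures]:
    """Timing measures computed from polar and from Cartesian execution
    variables of the same trajectory.

    The Cartesian route converts every sample's state to its release
    velocity vector and reconstructs the ball launch from that vector alone
    (plus the task's throw direction); both parameterizations describe the
    same physical launches, so the measures coincide.
    """
    et_polar, _ = _error_trajectory_full(traj, config)
    polar = compute_timing_measures(et_polar, traj.release_index, rule)

    th = np.radians(traj.angle)
    thd = np.radians(traj.velocities())
    L = config.lever_length
    vx = -L * thd * np.sin(th)
    vy = L * thd * np.cos(th)
    speed = np.hypot(vx, vy)
    sgn = config.direction_sign
    px, py = config.lever_pivot
    with np.errstate(invalid="ignore", divide="ignore"):
        rx = np.where(speed > 0, sgn * vy / speed, np.cos(th))
        ry = np.where(speed > 0, -sgn * vx / speed, np.sin(th))
    x0 = px + L * rx
    y0 = py + L * ry
    err, post_hit, tcl, _ = score_launches(x0, y0, vx, vy, config)
    arr = ScoreArrays(
        error=err,
        post_hit=post_hit,
        time_of_closest_approach=tcl,
        category=classify_error(err, post_hit, config),
    )
    et_cart = _assemble(traj, arr, config)
    cartesian = compute_timing_measures(et_cart, traj.release_index, rule)
    return polar, cartesian
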