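"""Execution-space mapping and solution-manifold extraction.

The execution space of a throw is spanned by the two release variables,
lever angle (deg) and angular speed in the task's throw direction (deg/s).
Evaluating the throw error over a grid of this space yields the error
surface; the subset with error below the success threshold (and no post
hit) is the solution manifold — the redundant set of perfect throws.  The
four classic task variants differ in the geometry of this manifold:

* U-shape: a curved valley, wider at low speeds;
* J-shape: a manifold that transitions discontinuously into post hits;
* Box-shape: shallow error gradients, manifold reaching low speeds;
* I-shape: a manifold parallel to the velocity axis (release speed is
  irrelevant), the singular control case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import TaskConfig
from .task_model import CATEGORY_HIT, CATEGORY_NAMES, score_states

__all__ = [
    "SolutionSpaceGrid",
    "ManifoldSlice",
    "evaluate_grid",
    "extract_manifold",
    "velocity_sensitivity",
    "manifold_area_fraction",
    "plot_grid",
]

DEFAULT_ANGLE_RANGE = (0.0, 180.0)
DEFAULT_VELOCITY_RANGE = (0.0, 1000.0)
DEFAULT_RESOLUTION = 300


@dataclass(frozen=True)
class SolutionSpaceGrid:
    """Error surface over a rectangular grid of release states.

    ``error[i, j]`` is the throw error (cm) for ``angle_axis[i]`` and
    ``velocity_axis[j]``; the velocity axis is the angular speed in the
    task's throw direction (the signed angular velocity is
    ``direction_sign * velocity_axis``).  ``category`` holds the integer
    codes of :data:`skittles.task_model.CATEGORY_NAMES`.
    """

    angle_axis: np.ndarray
    velocity_axis: np.ndarray
    error: np.ndarray
    post_hit: np.ndarray
    category: np.ndarray
    config: TaskConfig = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        na, nv = self.angle_axis.size, self.velocity_axis.size
        if self.error.shape != (na, nv):
            raise ValueError("error matrix shape must be (n_angles, n_velocities)")
        if self.post_hit.shape != (na, nv) or self.category.shape != (na, nv):
            raise ValueError("post_hit and category must match the error shape")

    def category_counts(self) -> dict[str, int]:
        """Number of grid cells per throw category."""
        return {
            name: int(np.count_nonzero(self.category == code))
            for code, name in CATEGORY_NAMES.items()
        }


@dataclass(frozen=True)
class ManifoldSlice:
    """Solution-manifold cross-section at one release angle: the velocity
    intervals (deg/s, cell-edge convention) whose throws hit the target
    below the success threshold."""

    angle: float
    velocity_intervals: list[tuple[float, float]]

    @property
    def total_width(self) -> float:
        return float(sum(hi - lo for lo, hi in self.velocity_intervals))


def _resolve_axes(angle_range, velocity_range, resolution):
    if isinstance(resolution, int):
        resolution = (resolution, resolution)
    na, nv = resolution
    if na < 2 or nv < 2:
        raise ValueError("resolution must be at least 2 per axis")
    a0, a1 = angle_range
    v0, v1 = velocity_range
    if not (a1 > a0 and v1 > v0):
        raise ValueError("axis ranges must be non-empty")
    return np.linspace(a0, a1, na), np.linspace(v0, v1, nv)


def evaluate_grid(
    config: TaskConfig,
    angle_range: tuple[float, float] = DEFAULT_ANGLE_RANGE,
    velocity_range: tuple[float, float] = DEFAULT_VELOCITY_RANGE,
    resolution: int | tuple[int, int] = DEFAULT_RESOLUTION,
) -> SolutionSpaceGrid:
    """Score every (angle, velocity) cell of a rectangular execution-space grid.

    Each cell holds exactly the result of scoring that release state on its
    own; the evaluation is deterministic and cache-free.
    """
    angles, vels = _resolve_axes(angle_range, velocity_range, resolution)
    A, V = np.meshgrid(angles, vels, indexing="ij")
    sgn = config.direction_sign
    arr = score_states(A.ravel(), sgn * V.ravel(), config)
    shape = A.shape
    return SolutionSpaceGrid(
        angle_axis=angles,
        velocity_axis=vels,
        error=arr.error.reshape(shape),
        post_hit=arr.post_hit.reshape(shape),
        category=arr.category.reshape(shape),
        config=config,
    )


def extract_manifold(grid: SolutionSpaceGrid) -> list[ManifoldSlice]:
    """Per-angle maximal runs of solution cells, as velocity intervals.

    A cell belongs to the manifold when its error is below the success
    threshold and the ball did not hit the post.  Runs are converted to
    intervals spanning the outer cell edges, so an isolated cell yields an
    interval one cell wide.
    """
    cfg = grid.config
    thr = cfg.success_threshold if cfg is not None else 1.1
    ok = (grid.error < thr) & ~grid.post_hit
    v = grid.velocity_axis
    dv = v[1] - v[0]
    slices: list[ManifoldSlice] = []
    for i, angle in enumerate(grid.angle_axis):
        row = ok[i]
        intervals: list[tuple[float, float]] = []
        j = 0
        n = row.size
        while j < n:
            if row[j]:
                k = j
                while k + 1 < n and row[k + 1]:
                    k += 1
                intervals.append((v[j] - dv / 2.0, v[k] + dv / 2.0))
                j = k + 1
            else:
                j += 1
        slices.append(ManifoldSlice(angle=float(angle), velocity_intervals=intervals))
    return slices


def velocity_sensitivity(grid: SolutionSpaceGrid) -> np.ndarray:
    """Per-angle coefficient of variation of error across the velocity axis.

    Post-hit cells are excluded.  A value near zero flags I-shape-like
    geometry (error independent of release speed); columns that are entirely
    post hits return NaN.  Columns whose mean error is numerically zero
    (below 1e-8 cm, i.e. every release is an exact solution) report zero
    sensitivity — the coefficient of variation of pure rounding noise
    carries no information.
    """
    out = np.full(grid.angle_axis.size, np.nan)
    for i in range(grid.angle_axis.size):
        vals = grid.error[i][~grid.post_hit[i]]
        if vals.size == 0:
            continue
        mean = float(np.mean(vals))
        if mean < 1e-8:
            out[i] = 0.0
            continue
        out[i] = float(np.std(vals)) / mean
    return out


def manifold_area_fraction(grid: SolutionSpaceGrid) -> float:
    """Fraction of grid cells on the solution manifold (hit category)."""
    return float(np.mean(grid.category == CATEGORY_HIT))


def plot_grid(grid: SolutionSpaceGrid, ax=None, show_colorbar: bool = True):
    """Convenience heatmap of the error surface in the classic colour code:
    green = hit, yellow = near, grey shades = miss, black = invalid."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    cfg = grid.config
    maxerr = cfg.max_display_error if cfg is not None else 40.0
    shade = np.clip(grid.error / maxerr, 0.0, 1.0)
    img = np.empty(grid.error.shape + (3,))
    img[...] = (0.85 - 0.6 * shade)[..., None]  # grey ramp for misses
    img[grid.category == 1] = (0.95, 0.85, 0.2)
    img[grid.category == 0] = (0.1, 0.7, 0.2)
    img[grid.category == 3] = (0.0, 0.0, 0.0)
    extent = (
        grid.velocity_axis[0],
        grid.velocity_axis[-1],
        grid.angle_axis[0],
        grid.angle_axis[-1],
    )
    ax.imshow(img, origin="lower", aspect="auto", extent=extent)
    ax.set_xlabel("release velocity (deg/s)")
    ax.set_ylabel("release angle (deg)")
    if cfg is not None:
        ax.set_title(cfg.name)
    return ax
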