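"""Delimited-text file formats for trajectories, grids and tables.

The task domain has no standard interchange format, so everything is plain
delimited text: diffable, portable, and exact.  Trajectory files are CSV
with columns ``time_ms, angle_deg[, angvel_deg_s], release`` (release is an
integer column with a single 1 marking the release sample); angles are
written at full precision so a write–read round trip is exact.  Grid
exports are TSV matrices with axis header row/column plus a JSON sidecar
documenting the integer category codes.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .solution_space import SolutionSpaceGrid
from .task_model import CATEGORY_NAMES
from .timing import ArmTrajectory

__all__ = [
    "TrajectoryFormatError",
    "read_trajectory_file",
    "write_trajectory_file",
    "write_grid",
]


class TrajectoryFormatError(ValueError):
    """A trajectory file violates the documented schema; names the line."""


def write_trajectory_file(traj: ArmTrajectory, path: str | Path) -> None:
    """Write a trajectory as CSV with full-precision angles.

    Columns: ``time_ms, angle_deg[, angvel_deg_s], release``; exactly one
    row has release = 1.
    """
    path = Path(path)
    has_vel = traj.angular_velocity is not None
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        header = ["time_ms", "angle_deg"] + (["angvel_deg_s"] if has_vel else []) + ["release"]
        w.writerow(header)
        for i in range(len(traj)):
            row = [repr(float(traj.time[i] * 1000.0)), repr(float(traj.angle[i]))]
            if has_vel:
                row.append(repr(float(traj.angular_velocity[i])))
            row.append("1" if i == traj.release_index else "0")
            w.writerow(row)


def read_trajectory_file(path: str | Path) -> ArmTrajectory:
    """Read a trajectory file, validating the schema.

    Raises :class:`TrajectoryFormatError` naming the offending line for
    malformed rows, non-uniform timestamps, or a missing/duplicated release
    marker.  The time base is rebuilt from the (validated) uniform sampling
    so a write–read round trip reproduces the trajectory exactly.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TrajectoryFormatError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        expected_base = ["time_ms", "angle_deg"]
        has_vel = "angvel_deg_s" in header
        want = expected_base + (["angvel_deg_s"] if has_vel else []) + ["release"]
        if header != want:
            raise TrajectoryFormatError(
                f"{path}: line 1: header {header!r} does not match expected {want!r}"
            )
        times, angles, vels, release_flags = [], [], [], []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(want):
                raise TrajectoryFormatError(
                    f"{path}: line {lineno}: expected {len(want)} fields, got {len(row)}"
                )
            try:
                times.append(float(row[0]))
                angles.append(float(row[1]))
                if has_vel:
                    vels.append(float(row[2]))
                release_flags.append(int(row[-1]))
            except ValueError as exc:
                raise TrajectoryFormatError(f"{path}: line {lineno}: {exc}") from None
    if not times:
        raise TrajectoryFormatError(f"{path}: no samples (header-only file)")
    t_ms = np.asarray(times)
    if t_ms.size >= 2:
        diffs = np.diff(t_ms)
        step = diffs[0]
        bad = np.nonzero(np.abs(diffs - step) > 1e-6)[0]
        if step <= 0 or bad.size:
            where = int(bad[0]) + 3 if bad.size else 2
            raise TrajectoryFormatError(
                f"{path}: line {where}: non-uniform sampling (gap or reversed timestamps)"
            )
        sample_rate = 1000.0 / step
    else:
        sample_rate = 1000.0
    marks = [i for i, r in enumerate(release_flags) if r == 1]
    if len(marks) != 1:
        raise TrajectoryFormatError(
            f"{path}: expected exactly one release marker, found {len(marks)}"
        )
    n = t_ms.size
    return ArmTrajectory(
        time=np.arange(n) / sample_rate,
        angle=np.asarray(angles),
        release_index=marks[0],
        angular_velocity=np.asarray(vels) if has_vel else None,
        sample_rate=sample_rate,
    )


def write_grid(grid: SolutionSpaceGrid, prefix: str | Path) -> dict[str, str]:
    """Export a solution-space grid as delimited matrices plus metadata.

    Writes ``<prefix>_error.tsv`` and ``<prefix>_category.tsv`` (first row =
    velocity axis, first column = angle axis) and ``<prefix>_meta.json``
    documenting the category codes.  Returns the mapping of outputs.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    out = {}

    def write_matrix(name: str, matrix: np.ndarray, fmt: str) -> None:
        p = prefix.parent / f"{prefix.name}_{name}.tsv"
        with p.open("w") as fh:
            fh.write("angle_deg\\velocity_deg_s\t")
            fh.write("\t".join(repr(float(v)) for v in grid.velocity_axis) + "\n")
            for i, a in enumerate(grid.angle_axis):
                fh.write(repr(float(a)) + "\t")
                fh.write("\t".join(fmt % v for v in matrix[i]) + "\n")
        out[name] = str(p)

    write_matrix("error", grid.error, "%.17g")
    write_matrix("category", grid.category, "%d")
    meta = {
        "category_codes": {str(k): v for k, v in CATEGORY_NAMES.items()},
        "angle_axis_deg": [float(grid.angle_axis[0]), float(grid.angle_axis[-1])],
        "velocity_axis_deg_s": [float(grid.velocity_axis[0]), float(grid.velocity_axis[-1])],
        "shape": list(grid.error.shape),
        "config": grid.config.name if grid.config is not None else None,
    }
    meta_path = prefix.parent / f"{prefix.name}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    out["meta"] = str(meta_path)
    return out
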