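"""Task configuration: geometry, physics constants and scoring thresholds.

A :class:`TaskConfig` fully specifies one variant of the virtual skittles
(tetherball) task: where the post and target sit in the workspace, the lever
arm the thrower rotates, the two-spring flight physics (natural frequency
``omega`` and damping time constant ``tau``), and the error thresholds that
define a successful hit.  The workspace origin (0, 0) is the rest position of
the two orthogonal springs; the post is usually, but not necessarily, centred
there.

Configurations are serialized as flat YAML files whose keys are exactly the
field names.  Four representative task variants (``u_shape``, ``j_shape``,
``box_shape``, ``i_shape``) ship with the package; they were produced by a
geometry search so that their solution manifolds reproduce the four
qualitative shapes the task is known for (see :mod:`skittles.solution_space`).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "TaskConfig",
    "load_config",
    "save_config",
    "load_task",
    "available_tasks",
]

_VALID_DIRECTIONS = ("clockwise", "counterclockwise")


@dataclass(frozen=True)
class TaskConfig:
    """Geometry, physics and thresholds of one skittles task variant.

    Distances are in cm, times in s, angles in degrees unless noted;
    ``omega`` is in rad/s.  ``tau`` may be ``inf`` for undamped flight.
    ``throw_direction`` states the direction of a regular throw and is used
    to resolve the sign of the angular velocity when execution variables are
    given in Cartesian workspace coordinates, and to orient default solution
    space axes.  Setting ``post_radius`` to 0 removes the post entirely
    (no collision is checked).
    """

    target_center: tuple[float, float]
    post_center: tuple[float, float] = (0.0, 0.0)
    post_radius: float = 25.0
    target_radius: float = 2.5
    ball_radius: float = 2.5
    lever_pivot: tuple[float, float] = (0.0, -150.0)
    lever_length: float = 40.0
    omega: float = 2.0 * math.pi
    tau: float = 10.0
    success_threshold: float = 1.1
    miss_threshold: float = 2.5
    max_display_error: float = 40.0
    throw_direction: str = "counterclockwise"
    sample_rate: float = 1000.0
    name: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_center", tuple(float(v) for v in self.target_center))
        object.__setattr__(self, "post_center", tuple(float(v) for v in self.post_center))
        object.__setattr__(self, "lever_pivot", tuple(float(v) for v in self.lever_pivot))
        if len(self.target_center) != 2 or len(self.post_center) != 2 or len(self.lever_pivot) != 2:
            raise ValueError("target_center, post_center and lever_pivot must be 2-vectors")
        for nm in ("target_radius", "ball_radius", "lever_length", "sample_rate"):
            if not getattr(self, nm) > 0:
                raise ValueError(f"{nm} must be > 0")
        if self.post_radius < 0:
            raise ValueError("post_radius must be >= 0 (0 removes the post)")
        if not (self.omega > 0):
            raise ValueError("omega must be > 0")
        if not (self.tau > 0):
            raise ValueError("tau must be > 0 (inf allowed)")
        if not (0 < self.success_threshold < self.miss_threshold <= self.max_display_error):
            raise ValueError(
                "thresholds must satisfy 0 < success_threshold < miss_threshold <= max_display_error"
            )
        if self.throw_direction not in _VALID_DIRECTIONS:
            raise ValueError(f"throw_direction must be one of {_VALID_DIRECTIONS}")

    # -- derived quantities -------------------------------------------------

    @property
    def period(self) -> float:
        """Duration of one full spring oscillation, 2*pi/omega (s)."""
        return 2.0 * math.pi / self.omega

    @property
    def contact_radius(self) -> float:
        """Centre-to-centre distance at which the ball touches the post."""
        return self.post_radius + self.ball_radius

    @property
    def direction_sign(self) -> int:
        """+1 for counterclockwise throws (positive angular velocity), -1 else."""
        return 1 if self.throw_direction == "counterclockwise" else -1

    def replace(self, **kwargs) -> "TaskConfig":
        return replace(self, **kwargs)

    def config_hash(self) -> str:
        """Stable short hash of the configuration contents."""
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


_HEADER = """\
# skittles task configuration (flat schema; keys are TaskConfig field names)
# units: lengths/positions in cm, times in s, omega in rad/s,
#        sample_rate in Hz, angles handled downstream in degrees
"""


def save_config(config: TaskConfig, path: str | Path) -> None:
    """Write a :class:`TaskConfig` as a flat, commented YAML file."""
    data = asdict(config)
    for key in ("target_center", "post_center", "lever_pivot"):
        data[key] = list(data[key])
    text = _HEADER + yaml.safe_dump(data, sort_keys=True, default_flow_style=None)
    Path(path).write_text(text)


def _from_mapping(data: dict, source: str) -> TaskConfig:
    if not isinstance(data, dict):
        raise ValueError(f"{source}: config file must contain a flat key/value mapping")
    known = set(TaskConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{source}: unknown config keys {sorted(unknown)}")
    if "target_center" not in data:
        raise ValueError(f"{source}: target_center is required")
    return TaskConfig(**data)


def load_config(path: str | Path) -> TaskConfig:
    """Load a :class:`TaskConfig` from a YAML file."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    return _from_mapping(data, str(path))


def available_tasks() -> list[str]:
    """Names of the task variants bundled with the package."""
    pkg = resources.files("skittles") / "tasks"
    return sorted(p.name[: -len(".yaml")] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_task(name: str) -> TaskConfig:
    """Load one of the bundled task variants by name (e.g. ``"u_shape"``)."""
    pkg = resources.files("skittles") / "tasks" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        raise KeyError(f"unknown bundled task {name!r}; available: {available_tasks()}") from None
    return _from_mapping(yaml.safe_load(text), f"bundled task {name}")
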