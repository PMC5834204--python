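"""End-to-end analysis pipeline: synthesize, analyze, summarize, regress.

The cohort simulator reproduces the structure of the practice study: a
group of simulated subjects each throws 240 times per day over several
daily sessions, with subject-specific release-jitter levels and
manifold-alignment rates.  Every throw is scored, its timing measures
computed, and sessions are reduced to summaries and per-day standardized
regressions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import TaskConfig, load_config
from .stats import (
    RegressionResult,
    SessionSummary,
    regress_error_on_timing,
    summaries_frame,
    summarize_session,
)
from .synth import (
    PracticeRamp,
    practice_ramp_for,
    generate_session,
    learning_schedule,
    throw_seed,
)
from .timing import analyze_throw

logger = logging.getLogger("skittles")

__all__ = ["CohortResult", "RunManifest", "simulate_learning_cohort", "run_pipeline"]


@dataclass
class CohortResult:
    """Output of a simulated practice cohort."""

    summaries: pd.DataFrame  # one row per subject and day
    regressions: dict[int, RegressionResult]  # per day, when >= 4 subjects
    ramp: PracticeRamp

    def day_means(self) -> pd.DataFrame:
        """Across-subject means (and SEMs) of the four measures per day."""
        cols = ["success_rate", "median_error", "median_timing_error", "mean_timing_window"]
        g = self.summaries.groupby("day")[cols]
        mean = g.mean()
        sem = g.sem().add_suffix("_sem")
        return pd.concat([mean, sem], axis=1)


def simulate_learning_cohort(
    config: TaskConfig,
    n_subjects: int = 10,
    days: int = 6,
    throws_per_day: int = 240,
    seed: int = 0,
    rule: str = "nearest_crossing",
    ramp: PracticeRamp | None = None,
    alignment_range: tuple[float, float] = (0.45, 1.0),
    jitter_scale_range: tuple[float, float] = (0.6, 1.6),
) -> CohortResult:
    """Simulate a practice cohort and compute all dependent measures.

    Subjects differ in two skill parameters drawn once per subject: how far
    along the task's movement-time ramp they progress (``alignment``, which
    governs the timing window they end up with) and a multiplier on the
    release-jitter schedule (which governs their timing error).  All
    randomness derives from ``seed``.
    """
    t_start = time.time()
    if ramp is None:
        ramp = practice_ramp_for(config)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(777,)))
    alignments = rng.uniform(*alignment_range, n_subjects)
    jitter_scales = rng.uniform(*jitter_scale_range, n_subjects)

    summaries: list[SessionSummary] = []
    for s in range(n_subjects):
        sched = learning_schedule(
            config,
            days=days,
            ramp=ramp,
            alignment=float(alignments[s]),
            jitter_scale=float(jitter_scales[s]),
            throws_per_day=throws_per_day,
            seed=throw_seed(seed, 0, s),
        )
        for day in range(1, days + 1):
            trajs = generate_session(sched, day, config)
            throws = [analyze_throw(traj, config, rule) for traj in trajs]
            summaries.append(summarize_session(throws, subject_id=f"S{s + 1:02d}", day=day))
        logger.info("subject %d/%d done (%.1fs)", s + 1, n_subjects, time.time() - t_start)

    frame = summaries_frame(summaries)
    regressions: dict[int, RegressionResult] = {}
    if n_subjects >= 4:
        for day in range(1, days + 1):
            day_summaries = [s for s in summaries if s.day == day]
            try:
                regressions[day] = regress_error_on_timing(day_summaries)
            except ValueError as exc:  # degenerate variance
                logger.warning("day %d regression skipped: %s", day, exc)
    return CohortResult(summaries=frame, regressions=regressions, ramp=ramp)


# ---------------------------------------------------------------------------
# file-producing pipeline


@dataclass
class RunManifest:
    """Provenance record of one pipeline run: configuration hash, seed and
    derived sub-seeds, stage outputs, and versions — enough to re-run the
    deterministic stages bit-identically."""

    config_path: str
    config_hash: str
    seed: int
    versions: dict[str, str]
    schedule: dict = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


DEFAULT_SCHEDULE = {
    "n_subjects": 10,
    "days": 6,
    "throws_per_day": 240,
    "rule": "nearest_crossing",
}


def run_pipeline(
    config: TaskConfig | str | Path,
    schedule: dict | None,
    out_dir: str | Path,
    seed: int = 0,
) -> RunManifest:
    """Run synthesize → analyze → summarize → regress and write all tables.

    ``schedule`` is a flat mapping overriding :data:`DEFAULT_SCHEDULE`
    (n_subjects, days, throws_per_day, rule, and any keyword accepted by
    :func:`simulate_learning_cohort`).  Outputs ``summaries.csv``,
    ``day_means.csv``, ``regressions.csv`` (when enough subjects) and
    ``manifest.json`` under ``out_dir``; a rerun with the same seed
    reproduces them bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(config, (str, Path)):
        config_path = str(config)
        config = load_config(config)
    else:
        config_path = f"<in-memory:{config.name}>"
    params = dict(DEFAULT_SCHEDULE)
    params.update(schedule or {})

    manifest = RunManifest(
        config_path=config_path,
        config_hash=config.config_hash(),
        seed=seed,
        versions={
            "skittles": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        schedule=params,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    stage = "simulate"
    try:
        cohort = simulate_learning_cohort(
            config,
            n_subjects=int(params["n_subjects"]),
            days=int(params["days"]),
            throws_per_day=int(params["throws_per_day"]),
            seed=seed,
            rule=str(params["rule"]),
        )
        stage = "summarize"
        summaries_path = out / "summaries.csv"
        cohort.summaries.to_csv(summaries_path, index=False)
        day_means_path = out / "day_means.csv"
        cohort.day_means().to_csv(day_means_path)
        manifest.stages.append(
            {"stage": "summarize", "outputs": [str(summaries_path), str(day_means_path)]}
        )
        stage = "regress"
        if cohort.regressions:
            rows = []
            for day, r in sorted(cohort.regressions.items()):
                rows.append(
                    {
                        "day": day,
                        "beta1_timing_error": r.beta1,
                        "beta2_timing_window": r.beta2,
                        "ci1_lo": r.ci1[0],
                        "ci1_hi": r.ci1[1],
                        "ci2_lo": r.ci2[0],
                        "ci2_hi": r.ci2[1],
                        "r_squared": r.r_squared,
                        "vif": r.vif,
                        "n_subjects": r.n_subjects,
                    }
                )
            reg_path = out / "regressions.csv"
            pd.DataFrame(rows).to_csv(reg_path, index=False)
            manifest.stages.append({"stage": "regress", "outputs": [str(reg_path)]})
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    return manifest
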