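"""Per-session descriptive measures and the standardized timing regression.

Each daily session is summarised by four dependent measures: success rate
(percent of hits), median performance error (errors are non-negative and
skewed, hence the median), median timing error and mean timing window.
Across the subjects of one day, performance error is regressed on the two
timing measures after z-scoring all three variables,

    y = beta1 * x1 - beta2 * x2,

where x1 is timing error and x2 is timing window.  The minus sign is a
reporting convention: the fit is unconstrained OLS, and beta2 is reported
as the coefficient entering with the minus sign (positive when a longer
window reduces error).  Variance-inflation factors flag collinearity
between the two predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .task_model import ThrowResult
from .timing import TimingMeasures

__all__ = [
    "SessionSummary",
    "RegressionResult",
    "summarize_session",
    "summaries_frame",
    "regress_error_on_timing",
]


@dataclass(frozen=True)
class SessionSummary:
    """Descriptive measures of one subject's daily session."""

    subject_id: str
    day: int
    success_rate: float  # percent of hit throws
    median_error: float  # cm
    median_timing_error: float  # ms
    mean_timing_window: float  # ms
    n_throws: int


@dataclass(frozen=True)
class RegressionResult:
    """Standardized regression of performance error on the timing measures."""

    beta1: float
    beta2: float
    ci1: tuple[float, float]
    ci2: tuple[float, float]
    r_squared: float
    vif: float
    n_subjects: int


def summarize_session(
    throws: Sequence[tuple[ThrowResult, TimingMeasures]],
    subject_id: str,
    day: int,
) -> SessionSummary:
    """Aggregate one day's throws: success rate over hits, median error,
    median timing error, mean timing window."""
    if len(throws) == 0:
        raise ValueError("cannot summarise an empty session")
    errors = np.array([t.error for t, _ in throws])
    hits = np.array([t.category == "hit" for t, _ in throws])
    te = np.array([m.timing_error for _, m in throws])
    tw = np.array([m.timing_window for _, m in throws])
    return SessionSummary(
        subject_id=subject_id,
        day=day,
        success_rate=100.0 * float(np.mean(hits)),
        median_error=float(np.median(errors)),
        median_timing_error=float(np.median(te)),
        mean_timing_window=float(np.mean(tw)),
        n_throws=len(throws),
    )


def summaries_frame(summaries: Iterable[SessionSummary]) -> pd.DataFrame:
    """Session summaries as a tidy DataFrame (one row per subject and day)."""
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "day": s.day,
                "success_rate": s.success_rate,
                "median_error": s.median_error,
                "median_timing_error": s.median_timing_error,
                "mean_timing_window": s.mean_timing_window,
                "n_throws": s.n_throws,
            }
            for s in summaries
        ]
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        raise ValueError("cannot z-score a variable with zero variance")
    return (x - np.mean(x)) / sd


def regress_error_on_timing(summaries: Sequence[SessionSummary]) -> RegressionResult:
    """Fit the standardized regression across the subjects of one day.

    All three variables are z-scored across subjects before the OLS fit, so
    the coefficients are standardized and invariant to affine rescaling of
    the raw measures.  beta2 is reported in the minus-sign convention of the
    model equation.  Requires at least 4 subjects and non-degenerate
    variance in every variable.
    """
    if len(summaries) < 4:
        raise ValueError("need at least 4 subjects for the regression")
    y = _zscore(np.array([s.median_error for s in summaries]))
    x1 = _zscore(np.array([s.median_timing_error for s in summaries]))
    x2 = _zscore(np.array([s.mean_timing_window for s in summaries]))
    X = sm.add_constant(np.column_stack([x1, x2]))
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    beta1 = float(fit.params[1])
    b2 = float(fit.params[2])
    ci1 = (float(ci[1][0]), float(ci[1][1]))
    # beta2 enters the model equation with a minus sign
    ci2 = (-float(ci[2][1]), -float(ci[2][0]))
    vif = float(variance_inflation_factor(X, 1))
    return RegressionResult(
        beta1=beta1,
        beta2=-b2,
        ci1=ci1,
        ci2=ci2,
        r_squared=float(fit.rsquared),
        vif=vif,
        n_subjects=len(summaries),
    )
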