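"""Drug time-course analysis: baseline normalization and sigmoid fits.

Metric values recorded at successive timepoints after a drug application are
normalized to the pre-drug baseline (timepoint 0 = 100%), and the normalized
response over time is summarised by a four-parameter logistic

    y(t) = y_min + (y_max - y_min) / (1 + exp(-(t - t50) / tau))

fit by least squares.  Decreasing responses are handled by allowing
``y_max < y_min`` rather than a separate sign parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


@dataclass
class TimeCourse:
    """One metric of one well over time; timepoint 0 is the pre-drug baseline."""

    well_id: str
    metric: str
    timepoints: np.ndarray  # minutes
    values: np.ndarray
    normalized: np.ndarray | None = None  # percent of baseline

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timepoints.shape != self.values.shape or self.timepoints.ndim != 1:
            raise ValueError("timepoints and values must be 1-d and equal length")
        if 0.0 not in self.timepoints:
            raise ValueError("baseline timepoint 0 is required")


class BaselineError(ValueError):
    """Raised when a well must be excluded for a non-positive baseline."""


def normalize_to_baseline(course: TimeCourse) -> TimeCourse:
    """Express every value as percent of the baseline (timepoint 0) value.

    A zero or negative baseline excludes the well: a ``BaselineError`` is
    raised carrying the well id so the caller can log the exclusion instead
    of propagating NaNs.
    """
    baseline = course.values[course.timepoints == 0.0][0]
    if baseline <= 0:
        raise BaselineError(
            f"well {course.well_id}: non-positive baseline ({baseline:g}) for "
            f"{course.metric}; well excluded"
        )
    return TimeCourse(
        course.well_id,
        course.metric,
        course.timepoints,
        course.values,
        normalized=100.0 * course.values / baseline,
    )


@dataclass
class SigmoidFit:
    y_min: float
    y_max: float
    t50: float  # minutes
    tau: float  # minutes
    rss: float
    converged: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.rss < 0:
            raise ValueError("rss must be non-negative")

    def predict(self, t) -> np.ndarray:
        return sigmoid(np.asarray(t, dtype=float),
                       self.y_min, self.y_max, self.t50, self.tau)


def sigmoid(t, y_min, y_max, t50, tau):
    z = np.clip(-(np.asarray(t, dtype=float) - t50) / tau, -500.0, 500.0)
    return y_min + (y_max - y_min) / (1.0 + np.exp(z))


def fit_sigmoid(course: TimeCourse) -> SigmoidFit:
    """Least-squares four-parameter logistic fit of a normalized time course.

    Non-convergence never raises: the best iterate is returned with
    ``converged=False``.  A flat course is flagged ``degenerate``.  The fitted
    curve is never worse (in RSS) than the flat mean model, because the flat
    model is among the starting points considered.
    """
    t = course.timepoints
    y = course.normalized if course.normalized is not None else course.values
    if t.size < 4:
        raise ValueError("need at least 4 timepoints for a 4-parameter fit")
    t_span = float(t.max() - t.min()) or 1.0
    tau0 = t_span / 5.0
    tau_max = 10.0 * max(float(t.max()), 1.0)
    lo = [-np.inf, -np.inf, -np.inf, 1e-9]
    hi = [np.inf, np.inf, np.inf, tau_max]

    def residuals(params):
        return sigmoid(t, *params) - y

    ymean = float(y.mean())
    starts = [
        [float(y.min()), float(y.max()), float(np.median(t)), tau0],
        [float(y.max()), float(y.min()), float(np.median(t)), tau0],
        [ymean, ymean, float(np.median(t)), tau0],  # flat-mean start
    ]
    # the (t50, tau) surface is multimodal under noise: seed a coarse grid
    for t50_0 in np.quantile(t, [0.25, 0.5, 0.75]):
        for tau_0 in (t_span / 10.0, t_span / 2.0):
            starts.append([float(y.min()), float(y.max()), float(t50_0), tau_0])
            starts.append([float(y.max()), float(y.min()), float(t50_0), tau_0])
    best = None
    for x0 in starts:
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, res)
    if best is None:  # pragma: no cover - least_squares is robust on bounded input
        return SigmoidFit(ymean, ymean, float(np.median(t)), tau0,
                          float(np.sum((y - ymean) ** 2)), converged=False,
                          degenerate=True)
    rss, res = best
    y_min, y_max, t50, tau = (float(v) for v in res.x)
    degenerate = abs(y_max - y_min) <= 1e-6 * max(1.0, abs(ymean))
    return SigmoidFit(y_min, y_max, t50, max(tau, 1e-9), rss,
                      converged=bool(res.success), degenerate=degenerate)


def fit_group_mean(courses: list[TimeCourse]) -> SigmoidFit:
    """Fit the sigmoid to the across-well mean of normalized time courses.

    All courses must share the same timepoint grid.
    """
    if not courses:
        raise ValueError("no time courses given")
    tp = courses[0].timepoints
    for c in courses[1:]:
        if not np.array_equal(c.timepoints, tp):
            raise ValueError("courses must share the same timepoints")
    ys = np.vstack([
        c.normalized if c.normalized is not None else c.values for c in courses
    ])
    mean_course = TimeCourse("GROUP_MEAN", courses[0].metric, tp,
                             ys.mean(axis=0), normalized=ys.mean(axis=0))
    return fit_sigmoid(mean_course)
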