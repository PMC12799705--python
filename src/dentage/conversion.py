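"""Score <-> dental age conversion: grid lookup and monotone logistic curves.

The third step of the method maps a summed maturity score to a dental age.
Two routes are provided:

* **grid** (default): piecewise-linear interpolation in a published
  :class:`~dentage.tables.ConversionGrid`.  Scores outside the grid clamp to
  the 6.0 / 16.0 endpoints with a flag rather than extrapolating — a sigmoid
  extrapolated beyond its calibration window fabricates precision.
* **curve**: a four-parameter logistic (4PL)
  ``score(age) = A + (K - A) / (1 + exp(-r (age - m)))``
  fitted to (age, score) anchors.  With ``A < K`` and ``r > 0`` the curve is
  strictly increasing, so a closed-form inverse exists on (A, K).  This is
  the generator used when calibrating new populations; the printed grid
  always takes precedence for bundled ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .core import validate_sex
from .errors import AgeOutOfRange, FitDiverged, NonMonotoneAnchors
from .tables import GRID_START, GRID_STOP, ConversionGrid, grid_ages

__all__ = [
    "DentalAgeEstimate",
    "LogisticCurve",
    "score_to_age",
    "age_to_score",
    "fit_logistic",
    "curve_to_grid",
]


@dataclass(frozen=True)
class DentalAgeEstimate:
    """A dental age (years, 2 dp) derived from a maturity score."""

    dental_age: float
    score: float
    clamped: bool = False
    method: str = "grid"


def score_to_age(grid: ConversionGrid, score: float) -> DentalAgeEstimate:
    """Dental age for a summed maturity score, by linear grid interpolation.

    Scores below the first / above the last grid score clamp to 6.0 / 16.0
    years with ``clamped=True``.
    """
    score = float(score)
    if not np.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    if score < grid.scores[0]:
        return DentalAgeEstimate(dental_age=GRID_START, score=score, clamped=True)
    if score > grid.scores[-1]:
        return DentalAgeEstimate(dental_age=GRID_STOP, score=score, clamped=True)
    age = float(np.interp(score, grid.scores, grid.ages))
    return DentalAgeEstimate(dental_age=round(age, 2), score=score)


def age_to_score(grid: ConversionGrid, age: float) -> float:
    """Grid score at an age in [6, 16]; linear interpolation off the 0.1 grid."""
    age = float(age)
    if not GRID_START <= age <= GRID_STOP:
        raise AgeOutOfRange(f"age must be within [{GRID_START}, {GRID_STOP}], got {age}")
    return float(np.interp(age, grid.ages, grid.scores))


@dataclass(frozen=True)
class LogisticCurve:
    """4PL sigmoid score(age) with a closed-form inverse.

    Parameters: lower asymptote ``A`` and upper asymptote ``K`` (score
    units), rate ``r`` (per year, > 0) and midpoint ``m`` (years, the age of
    fastest score gain).
    """

    lower: float
    upper: float
    rate: float
    midpoint: float
    residuals: Optional[np.ndarray] = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"need lower < upper, got {self.lower} >= {self.upper}")
        if not self.rate > 0:
            raise ValueError(f"need rate > 0, got {self.rate}")

    def __call__(self, age) -> np.ndarray | float:
        age = np.asarray(age, dtype=float)
        out = self.lower + (self.upper - self.lower) / (1.0 + np.exp(-self.rate * (age - self.midpoint)))
        return float(out) if out.ndim == 0 else out

    def inverse(self, score) -> np.ndarray | float:
        """Age at which the curve attains ``score``; defined on (A, K)."""
        score = np.asarray(score, dtype=float)
        if np.any(score <= self.lower) or np.any(score >= self.upper):
            raise ValueError("score outside the curve's open range (lower, upper)")
        out = self.midpoint - np.log((self.upper - self.lower) / (score - self.lower) - 1.0) / self.rate
        return float(out) if out.ndim == 0 else out


def _logistic(age, lower, upper, rate, midpoint):
    return lower + (upper - lower) / (1.0 + np.exp(-rate * (age - midpoint)))


def fit_logistic(anchors: Sequence[Tuple[float, float]]) -> LogisticCurve:
    """Least-squares 4PL fit to (age, score) anchors.

    Requires at least four anchors with strictly increasing ages and scores
    (four parameters; monotonicity is what the curve models).  The fit is
    retried from a few deterministic starting points before giving up with
    :class:`FitDiverged`.  The returned curve carries the per-anchor
    residuals (observed - fitted) in ``curve.residuals``.
    """
    anchors = [(float(a), float(s)) for a, s in anchors]
    if len(anchors) < 4:
        raise FitDiverged(f"need at least 4 anchors to fit a 4PL curve, got {len(anchors)}")
    ages = np.array([a for a, _ in anchors])
    scores = np.array([s for _, s in anchors])
    if not (np.all(np.diff(ages) > 0) and np.all(np.diff(scores) > 0)):
        raise NonMonotoneAnchors("anchor ages and scores must both be strictly increasing")

    span = scores[-1] - scores[0]
    age_span = ages[-1] - ages[0]
    starts = [
        # (lower, upper, rate, midpoint)
        (scores[0] - 0.1 * span, scores[-1] + 0.1 * span, 2.0 / age_span, float(np.median(ages))),
        (scores[0] - 0.5 * span, scores[-1] + 0.05 * span, 4.0 / age_span, ages[0] + 0.3 * age_span),
        (0.0, scores[-1] + 0.5 * span, 0.5, float(np.mean(ages))),
    ]
    lower_bounds = [-np.inf, scores[-1], 1e-6, ages[0] - 5 * age_span]
    upper_bounds = [scores[0], np.inf, 10.0, ages[-1] + 5 * age_span]

    last_err = None
    for p0 in starts:
        p0 = np.clip(p0, lower_bounds, upper_bounds)
        try:
            popt, _ = curve_fit(
                _logistic, ages, scores, p0=p0,
                bounds=(lower_bounds, upper_bounds), maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        lower, upper, rate, midpoint = map(float, popt)
        if lower < upper and rate > 0:
            residuals = scores - _logistic(ages, *popt)
            return LogisticCurve(lower, upper, rate, midpoint, residuals=residuals)
    raise FitDiverged(f"4PL fit did not converge from any starting point ({last_err})")


def curve_to_grid(curve: LogisticCurve, sex: str) -> ConversionGrid:
    """Discretize a fitted curve onto the 6.0-16.0 age grid (scores at 2 dp).

    Rounding can introduce ties on a near-flat curve; ties are broken by the
    minimal upward nudge at the third decimal and the grid is flagged
    ``nudged=True``.
    """
    ages = grid_ages()
    scores = np.round(curve(ages), 2)
    nudged = False
    for i in range(1, len(scores)):
        if scores[i] <= scores[i - 1]:
            scores[i] = round(scores[i - 1] + 0.001, 3)
            nudged = True
    return ConversionGrid(sex=validate_sex(sex), ages=ages, scores=scores, nudged=nudged)
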