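"""Diurnal parameter profiles: circadian variation of model parameters.

Insulin sensitivity (and potentially other control parameters) varies over
the day; a model with time-constant parameters accumulates its worst errors
at night.  The day is split into four equal six-hour periods (0:00-6:00,
6:00-12:00, 12:00-18:00, 18:00-0:00) and the profiled parameter is trained
separately against the CGMS samples of each period, while the simulation
always runs continuously over the whole window (digestion and insulin
kinetics cross period boundaries).  The four trained multipliers become
knots of a periodic cubic spline over minute-of-day, anchored at the period
midpoints (3:00, 9:00, 15:00, 21:00), so the resulting 24-h multiplier
curve is smooth everywhere - including midnight - and passes through each
period's trained value at its centre.  Spline overshoot beyond the
multiplier bounds is clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .identification import (
    FitnessEvaluator,
    FitResult,
    ParameterSpace,
    TrainingConfig,
    train,
)
from .lifestyle_log import MINUTES_PER_DAY, PatientLog

__all__ = ["PERIOD_EDGES", "PERIOD_MIDPOINTS", "DiurnalProfile", "train_diurnal"]

#: Boundaries of the four six-hour day periods, minutes of day.
PERIOD_EDGES = (0.0, 360.0, 720.0, 1080.0, 1440.0)
#: Spline knots sit at the period midpoints.
PERIOD_MIDPOINTS = (180.0, 540.0, 900.0, 1260.0)


@dataclass
class DiurnalProfile:
    """A periodic 24-h multiplier curve for one or more model parameters."""

    param_names: tuple[str, ...]
    knots: tuple[float, float, float, float]
    lower: float = 0.2
    upper: float = 5.0
    _spline: CubicSpline = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.knots) != len(PERIOD_MIDPOINTS):
            raise ValueError("one knot per day period is required")
        x = np.array(PERIOD_MIDPOINTS + (PERIOD_MIDPOINTS[0] + MINUTES_PER_DAY,))
        y = np.array(self.knots + (self.knots[0],))
        self._spline = CubicSpline(x, y, bc_type="periodic")

    def value(self, minute_of_day: float) -> float:
        return float(self.multipliers(minute_of_day))

    def multipliers(self, minute_of_day: float | np.ndarray) -> np.ndarray:
        """Periodic spline evaluation, clipped to the multiplier bounds."""
        m = np.mod(np.asarray(minute_of_day, dtype=float) - PERIOD_MIDPOINTS[0], MINUTES_PER_DAY)
        raw = self._spline(m + PERIOD_MIDPOINTS[0])
        return np.clip(raw, self.lower, self.upper)

    def is_constant(self, tol: float = 0.0) -> bool:
        return max(self.knots) - min(self.knots) <= tol

    def to_dict(self) -> dict:
        return {
            "parameters": list(self.param_names),
            "knots": list(self.knots),
            "period_edges": list(PERIOD_EDGES),
            "bounds": [self.lower, self.upper],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DiurnalProfile":
        lower, upper = payload.get("bounds", [0.2, 5.0])
        return cls(
            param_names=tuple(payload["parameters"]),
            knots=tuple(payload["knots"]),
            lower=lower,
            upper=upper,
        )


def train_diurnal(
    log: PatientLog,
    space: ParameterSpace,
    config: TrainingConfig,
    *,
    refine: bool = True,
) -> tuple[DiurnalProfile, list[FitResult]]:
    """Train a diurnal profile of the parameters in ``space``.

    Runs the configured identification method once per day period, scoring
    only the CGMS samples whose minute-of-day falls in that period; the
    simulation always covers the whole window.  A period without CGMS
    samples inherits the neutral multiplier 1.0 (i.e. the already-trained
    global value of the parameter) with a warning.

    ``space`` holds the profiled parameter(s) - typically the single
    insulin-sensitivity parameter ``K_xi`` - with the globally trained
    values as its reference.  Returns the smoothed profile and the four
    per-period fit results.
    """
    if log.duration < MINUTES_PER_DAY:
        raise ValueError("diurnal training needs at least one full day of data")
    minute_of_day = log.minute_of_day(log.cgms_times())
    knots: list[float] = []
    results: list[FitResult] = []
    for p in range(4):
        mask = (PERIOD_EDGES[p] <= minute_of_day) & (minute_of_day < PERIOD_EDGES[p + 1])
        if not mask.any():
            warnings.warn(
                f"day period {p} has no CGMS samples; keeping the global value",
                stacklevel=2,
            )
            knots.append(1.0)
            results.append(
                FitResult(
                    multipliers={n: 1.0 for n in space.names},
                    params=space.reference,
                    fitness=float("nan"),
                    n_evaluations=0,
                    method="inherited",
                )
            )
            continue
        evaluator = FitnessEvaluator(log, space, sample_mask=mask)
        result = train(log, space, config, refine=refine, evaluator=evaluator)
        # a single multiplier curve is shared by all profiled parameters
        knots.append(float(np.mean(result.vector(space.names))))
        results.append(result)
    profile = DiurnalProfile(
        param_names=space.names,
        knots=tuple(knots),
        lower=space.lower,
        upper=space.upper,
    )
    return profile, results
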