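"""Prediction protocols and figures of merit.

Two protocols probe complementary questions: the *meal-wise* test starts
the model fresh at each meal (no knowledge of earlier meals or injections)
and runs it for 1-6 h, measuring how errors accumulate with the prediction
horizon; the *full-log* run simulates the entire record continuously,
optionally restarting the predicted glucose at every fingerstick
measurement the way a lifestyle application would.

Errors are summarized as mean absolute error, maximal absolute error,
error variance and RMSE (all mmol/l), and clinically through Clarke Error
Grid Analysis: each (reference, prediction) pair falls in one zone from A
(benign) to E (dangerous), and the A+B fraction is the clinically
acceptable share.  A sliding-window cross-validation estimates the 1-h
predictive RMSE of the fully trained pipeline, and a Welch two-sample
t-test supports claims that one protocol improves on another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import engine
from .absorption import AbsorptionParams
from .glycemia import GlycemiaParams, steady_state
from .identification import FitnessEvaluator, ParameterSpace, TrainingConfig, train
from .lifestyle_log import MG_DL_PER_MMOL_L, MINUTES_PER_DAY, PatientLog, slice_window

__all__ = [
    "PredictionResult",
    "EGAReport",
    "error_metrics",
    "ega_classify",
    "ega_report",
    "full_run",
    "meal_wise_test",
    "cross_validate",
    "improvement_ttest",
]


@dataclass
class PredictionResult:
    """Aligned (time, predicted, reference) series under one protocol."""

    times: np.ndarray
    predicted: np.ndarray
    reference: np.ndarray
    protocol: str = ""

    def __post_init__(self) -> None:
        if not len(self.times) == len(self.predicted) == len(self.reference):
            raise ValueError("series must be aligned on identical timestamps")

    @property
    def errors(self) -> np.ndarray:
        return self.predicted - self.reference


@dataclass
class EGAReport:
    """Clarke error-grid zoning of a prediction series."""

    zones: np.ndarray  # one label 'A'..'E' per pair
    fractions: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.zones)
        self.fractions = {
            z: float(np.count_nonzero(self.zones == z)) / n for z in "ABCDE"
        }

    @property
    def acceptable(self) -> float:
        """Clinically acceptable share: zone A + zone B."""
        return self.fractions["A"] + self.fractions["B"]


def error_metrics(result: PredictionResult) -> dict[str, float]:
    """Average |error|, max |error|, error variance and RMSE (mmol/l)."""
    e = result.errors
    if e.size == 0:
        raise ValueError("no prediction pairs to evaluate")
    return {
        "average_error": float(np.mean(np.abs(e))),
        "max_error": float(np.max(np.abs(e))),
        "variance": float(np.var(e)),
        "rmse": float(np.sqrt(np.mean(e * e))),
    }


def ega_classify(
    predicted: float | np.ndarray, reference: float | np.ndarray
) -> np.ndarray:
    """Clarke error-grid zone for prediction/reference pairs (mmol/l).

    The zone geometry follows the original error-grid publication, with the
    inequalities evaluated in mg/dl.  Boundary points go to the less severe
    zone (A tested first, then E, C, D, B as the remainder).  Zone sketch,
    with x = reference, y = predicted in mg/dl:

    - A: y within 20% of x, or both below 70
    - E: gross mismatch (x <= 70 but y >= 180, or x >= 180 but y <= 70)
    - C: overcorrection band (70 <= x <= 290 and y >= x + 110, or
         130 <= x <= 180 and y <= 7/5 x - 182)
    - D: dangerous failure to detect (x >= 240 with 70 <= y <= 180, or
         x <= 175/3 with 70 <= y <= 180, or 175/3 <= x <= 70 with y >= 6/5 x)
    - B: everything else
    """
    scalar = np.ndim(predicted) == 0 and np.ndim(reference) == 0
    x = np.atleast_1d(np.asarray(reference, dtype=float)) * MG_DL_PER_MMOL_L
    y = np.atleast_1d(np.asarray(predicted, dtype=float)) * MG_DL_PER_MMOL_L
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("glucose values must be > 0")
    x, y = np.broadcast_arrays(x, y)

    zone_a = ((x <= 70) & (y <= 70)) | (np.abs(y - x) <= 0.2 * x)
    zone_e = ((x >= 180) & (y <= 70)) | ((x <= 70) & (y >= 180))
    zone_c = ((x >= 70) & (x <= 290) & (y >= x + 110)) | (
        (x >= 130) & (x <= 180) & (y <= (7.0 / 5.0) * x - 182)
    )
    zone_d = ((x >= 240) & (y >= 70) & (y <= 180)) | (
        (x <= 175.0 / 3.0) & (y >= 70) & (y <= 180)
    ) | ((x >= 175.0 / 3.0) & (x <= 70) & (y >= (6.0 / 5.0) * x))

    zones = np.full(x.shape, "B")
    zones[zone_d] = "D"
    zones[zone_c] = "C"
    zones[zone_e] = "E"
    zones[zone_a] = "A"
    return str(zones[0]) if scalar else zones


def ega_report(result: PredictionResult) -> EGAReport:
    return EGAReport(zones=np.atleast_1d(ega_classify(result.predicted, result.reference)))


# -- protocols -----------------------------------------------------------------


def _simulate_against_cgms(
    log: PatientLog,
    params: GlycemiaParams,
    profile,
    absorption_params: AbsorptionParams | None,
    restart: bool,
    step: float,
    G0: float | None = None,
) -> PredictionResult:
    times = log.cgms_times()
    prep = engine.prepare_window(
        log, absorption_params, step=step, restart=restart, record_times=times, G0=G0
    )
    if prep.G0 is None:
        prep.G0 = steady_state(params)[0]
    out = engine.run_batch(prep, engine.params_to_batch(params), profile=profile)
    if not out["ok"].all():
        raise FloatingPointError("simulation lost finiteness")
    return PredictionResult(times=times, predicted=out["G"][0], reference=log.cgms_values())


def full_run(
    log: PatientLog,
    params: GlycemiaParams,
    profile=None,
    *,
    restart: bool = True,
    absorption_params: AbsorptionParams | None = None,
    step: float = 1.0,
) -> PredictionResult:
    """Continuous simulation of the whole log scored against all CGMS samples.

    With ``restart`` the predicted glucose is reset to each fingerstick
    value; without fingersticks in the log both modes coincide.
    """
    result = _simulate_against_cgms(log, params, profile, absorption_params, restart, step)
    result.protocol = f"full_run(restart={'on' if restart else 'off'})"
    return result


def meal_wise_test(
    log: PatientLog,
    params: GlycemiaParams,
    profile=None,
    horizons: tuple[float, ...] = (60.0, 120.0, 240.0, 360.0),
    *,
    absorption_params: AbsorptionParams | None = None,
    anchor_window: float = 10.0,
    step: float = 1.0,
) -> dict[float, dict]:
    """Fresh-start prediction from each meal over several horizons.

    For every meal, the model starts from the CGMS value nearest the meal
    time (within ``anchor_window`` minutes; otherwise the meal is skipped
    with a warning), with empty stomach and depots and steady-state
    insulin, ignoring all earlier meals and injections.  Events inside the
    horizon are applied.  Pairs are pooled across meals per horizon; the
    returned dict maps horizon -> {'result', 'metrics', 'ega', 'n_meals'}.
    """
    import warnings

    cgms_t = log.cgms_times()
    cgms_v = log.cgms_values()
    if cgms_t.size == 0:
        raise ValueError("meal-wise testing requires CGMS data")
    out: dict[float, dict] = {}
    for horizon in horizons:
        t_all, p_all, r_all = [], [], []
        n_meals = 0
        for meal in log.meals:
            j = int(np.argmin(np.abs(cgms_t - meal.time)))
            if abs(cgms_t[j] - meal.time) > anchor_window:
                warnings.warn(
                    f"meal at t={meal.time:.0f} min has no CGMS anchor within "
                    f"{anchor_window:.0f} min; skipped",
                    stacklevel=2,
                )
                continue
            width = min(horizon, log.duration - meal.time)
            if width <= 0:
                continue
            window = slice_window(log, meal.time, width)
            mask = window.cgms_times() > 0  # score strictly after the start
            if not mask.any():
                continue
            result = _simulate_against_cgms(
                window, params, profile, absorption_params,
                restart=False, step=step, G0=float(cgms_v[j]),
            )
            n_meals += 1
            t_all.append(result.times[mask] + meal.time)
            p_all.append(result.predicted[mask])
            r_all.append(result.reference[mask])
        if not t_all:
            raise ValueError(f"no meal admitted a {horizon:.0f}-min meal-wise window")
        pooled = PredictionResult(
            times=np.concatenate(t_all),
            predicted=np.concatenate(p_all),
            reference=np.concatenate(r_all),
            protocol=f"meal_wise(horizon={horizon:.0f}min)",
        )
        out[horizon] = {
            "result": pooled,
            "metrics": error_metrics(pooled),
            "ega": ega_report(pooled),
            "n_meals": n_meals,
        }
    return out


def cross_validate(
    log: PatientLog,
    train_width_days: float,
    *,
    positions: int = 10,
    step_min: float = 180.0,
    space: ParameterSpace | None = None,
    config: TrainingConfig | None = None,
    refine: bool = False,
    horizon: float = 60.0,
    absorption_params: AbsorptionParams | None = None,
) -> dict:
    """Sliding-window cross-validation of the 1-h meal-wise prediction error.

    The training window of ``train_width_days`` slides from t = 0 in steps
    of ``step_min`` to ``positions`` placements; at each placement the
    personalized parameters are trained on the window and the 1-h meal-wise
    RMSE is measured on the meals outside it.  Returns the per-fold RMSEs
    and their mean.
    """
    width = train_width_days * MINUTES_PER_DAY
    last_start = (positions - 1) * step_min
    if width + last_start > log.duration:
        feasible = int((log.duration - width) // step_min) + 1
        raise ValueError(
            f"log too short for {positions} positions; at most {max(feasible, 0)} fit"
        )
    space = space or ParameterSpace.preset(3)
    config = config or TrainingConfig.ga_fast()
    fold_rmse: list[float] = []
    for p in range(positions):
        start = p * step_min
        window = slice_window(log, start, width)
        fitted = train(window, space, config, refine=refine)
        eval_meals = [m for m in log.meals if not start <= m.time < start + width]
        pooled_p, pooled_r = [], []
        cgms_t, cgms_v = log.cgms_times(), log.cgms_values()
        for meal in eval_meals:
            j = int(np.argmin(np.abs(cgms_t - meal.time)))
            if abs(cgms_t[j] - meal.time) > 10.0:
                continue
            eval_width = min(horizon, log.duration - meal.time)
            if eval_width <= 0:
                continue
            sub = slice_window(log, meal.time, eval_width)
            mask = sub.cgms_times() > 0
            if not mask.any():
                continue
            result = _simulate_against_cgms(
                sub, fitted.params, None, absorption_params,
                restart=False, step=1.0, G0=float(cgms_v[j]),
            )
            pooled_p.append(result.predicted[mask])
            pooled_r.append(result.reference[mask])
        if not pooled_p:
            raise ValueError(f"fold at start={start:.0f} min has no evaluation meals")
        e = np.concatenate(pooled_p) - np.concatenate(pooled_r)
        fold_rmse.append(float(np.sqrt(np.mean(e * e))))
    return {
        "mean_rmse": float(np.mean(fold_rmse)),
        "fold_rmse": fold_rmse,
        "train_width_days": train_width_days,
        "positions": positions,
    }


def improvement_ttest(
    errors_a: np.ndarray, errors_b: np.ndarray, alpha: float = 0.05
) -> dict[str, float | bool]:
    """Welch two-sample t-test between two error series.

    Returns the t statistic, the two-sided p value and whether the
    difference is significant at level ``alpha``.  Two identical
    zero-variance samples yield t = 0, p = 1.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both series need at least 2 samples")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return {"t": 0.0, "p": 1.0, "significant": False}
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p), "significant": bool(p < alpha)}
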