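"""Virtual patients: synthetic lifestyle logs with known ground truth.

The clinical logs this kind of model is trained on (multi-day outpatient
records with meals, subcutaneous insulin, CGMS traces) are not publicly
available, so testing and calibration run on virtual patients: a planted
parameter vector (optionally with a planted diurnal insulin-sensitivity
profile) drives the forward model over a realistic meal/bolus/basal
schedule, and the resulting true glucose trace is corrupted with a CGMS
error model before being written into a standard lifestyle log.

The CGMS error is multiplicative - a white component plus a slowly varying
AR(1) drift whose amplitude grows with sensor age - calibrated so the mean
absolute relative error is ~17% and the median absolute difference is
~1.4 mmol/l at typical diabetic glucose levels, matching the error range
clinical evaluations report for outpatient CGMS use.  Fingerstick
self-measurements before each main meal carry a small independent error
(5% coefficient of variation by default; quantitative meter specifications
vary, this is a plausible placeholder).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diurnal import DiurnalProfile
from .glycemia import GlycemiaParams, simulate, steady_state
from .identification import PRESET_PARAMS
from .lifestyle_log import (
    MINUTES_PER_DAY,
    GlucoseMeasurement,
    InsulinEvent,
    MealEvent,
    NutrientComposition,
    PatientLog,
)

__all__ = [
    "NoiseSpec",
    "ScheduleSpec",
    "VirtualPatientSpec",
    "sample_patient",
    "generate_log",
]

#: Per-meal nutrient templates (g); starch portions carry a glycemic index.
MEAL_TEMPLATES: dict[str, NutrientComposition] = {
    "breakfast": NutrientComposition(15.0, [(40.0, 0.9)], 10.0, 15.0, 4.0),
    "lunch": NutrientComposition(10.0, [(60.0, 0.8)], 20.0, 30.0, 8.0),
    "dinner": NutrientComposition(10.0, [(50.0, 0.7)], 15.0, 25.0, 6.0),
}


@dataclass(frozen=True)
class NoiseSpec:
    """CGMS + fingerstick measurement error model.

    The total stationary relative error sd is ``mean_relative_error *
    sqrt(pi/2)`` (the mean |N(0, s)| is s sqrt(2/pi)); ``drift_fraction``
    of its variance lives in an AR(1) drift with time constant
    ``drift_tau_min`` whose sd grows by ``sensor_age_slope`` per sensor-day
    (centred on day 1, so a 3-day log averages out to the target).
    """

    mean_relative_error: float = 0.17
    drift_fraction: float = 0.4
    drift_tau_min: float = 120.0
    sensor_age_slope: float = 0.10
    fingerstick_cv: float = 0.05

    def __post_init__(self) -> None:
        for name in dataclasses.asdict(self):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.drift_fraction <= 1:
            raise ValueError("drift_fraction must lie in [0, 1]")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 120.0, 0.0, 0.0)


@dataclass(frozen=True)
class ScheduleSpec:
    """Daily meal / insulin routine of a virtual patient."""

    meal_minutes: tuple[float, ...] = (450.0, 750.0, 1110.0)  # 7:30, 12:30, 18:30
    meal_names: tuple[str, ...] = ("breakfast", "lunch", "dinner")
    meal_time_jitter_sd: float = 20.0  # min
    meal_size_jitter_sd: float = 0.15  # relative (log-normal)
    iu_per_10g_carb: float = 0.6
    bolus_jitter: float = 0.20  # +-20%: dosing by experience, not perfection
    bolus_product: str = "rapid_analog"
    bolus_t_max_i: float = 55.0
    basal_dose_iu: float = 10.0
    basal_minute: float = 1320.0  # 22:00
    basal_product: str = "long_analog"
    basal_t_max_i: float = 600.0
    fingerstick_lead_min: float = 10.0
    cgms_cadence_min: float = 5.0


@dataclass(frozen=True)
class VirtualPatientSpec:
    """Everything needed to reproduce one virtual patient end to end."""

    multipliers: dict[str, float] = field(default_factory=dict)
    diurnal_knots: tuple[float, float, float, float] | None = None
    diurnal_param: str = "K_xi"
    body_weight_kg: float = 80.0
    base_params: GlycemiaParams | None = None
    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def true_params(self) -> GlycemiaParams:
        base = self.base_params or GlycemiaParams(body_weight_kg=self.body_weight_kg)
        base = dataclasses.replace(base, body_weight_kg=self.body_weight_kg)
        return base.with_multipliers(self.multipliers)

    def true_profile(self) -> DiurnalProfile | None:
        if self.diurnal_knots is None:
            return None
        return DiurnalProfile(param_names=(self.diurnal_param,), knots=tuple(self.diurnal_knots))


def sample_patient(
    template: VirtualPatientSpec | None = None,
    seed: int = 0,
    *,
    names: tuple[str, ...] = PRESET_PARAMS[3],
    sd: float = 0.2,
    lower: float = 0.2,
    upper: float = 5.0,
) -> VirtualPatientSpec:
    """Draw a virtual patient with log-normal parameter multipliers.

    Multipliers have median 1.0 and log-sd ``sd``, truncated to the
    identification bounds; ``sd = 0`` plants the reference patient exactly.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    multipliers = {
        name: float(np.clip(np.exp(rng.normal(0.0, sd)), lower, upper)) for name in names
    }
    template = template or VirtualPatientSpec()
    return dataclasses.replace(template, multipliers=multipliers, seed=seed)


def _jitter_composition(
    comp: NutrientComposition, factor: float
) -> NutrientComposition:
    return NutrientComposition(
        comp.monosaccharide_g * factor,
        [(m * factor, gi) for m, gi in comp.starch_portions],
        comp.lipid_g * factor,
        comp.protein_g * factor,
        comp.fiber_g * factor,
    )


def _cgms_noise(rng: np.random.Generator, times: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Relative CGMS error per sample: white + sensor-age-scaled AR(1) drift."""
    if spec.mean_relative_error == 0:
        return np.zeros(times.size)
    sd_total = spec.mean_relative_error * np.sqrt(np.pi / 2.0)
    sd_white = sd_total * np.sqrt(1.0 - spec.drift_fraction)
    sensor_day = np.floor(times / MINUTES_PER_DAY) % 6  # six-day sensor lifetime
    sd_drift = (
        sd_total
        * np.sqrt(spec.drift_fraction)
        * (1.0 + spec.sensor_age_slope * (sensor_day - 1.0))
    )
    white = rng.normal(0.0, sd_white, times.size)
    drift = np.zeros(times.size)
    if spec.drift_fraction > 0:
        dt = np.diff(times, prepend=times[0])
        phi = np.exp(-dt / spec.drift_tau_min)
        innov = rng.normal(0.0, 1.0, times.size)
        drift[0] = sd_drift[0] * innov[0]
        for i in range(1, times.size):
            drift[i] = phi[i] * drift[i - 1] + np.sqrt(1.0 - phi[i] ** 2) * sd_drift[i] * innov[i]
    return white + drift


def generate_log(
    spec: VirtualPatientSpec, days: int = 3
) -> tuple[PatientLog, pd.DataFrame]:
    """Generate a multi-day lifestyle log and its noise-free ground truth.

    The log starts at midnight (day phase 0) and contains, per day, the
    scheduled main meals with jittered times and sizes, a
    carbohydrate-proportional (deliberately imperfect) bolus at each meal,
    one bedtime basal dose, a fingerstick before each main meal and CGMS
    samples every 5 minutes.  The true model trajectory - simulated from
    the basal steady state of the planted parameters, with the planted
    diurnal profile if any - is returned alongside as a DataFrame
    (``t_min``, ``G_mmol_l``, ``I_pM``); the log's measurements are the
    truth plus the configured noise.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(spec.seed)
    rng_sched, rng_cgms, rng_fs = rng.spawn(3)
    sched = spec.schedule
    duration = days * MINUTES_PER_DAY

    meals: list[MealEvent] = []
    insulins: list[InsulinEvent] = []
    fs_times: list[float] = []
    for day in range(days):
        for base_minute, name in zip(sched.meal_minutes, sched.meal_names):
            t = day * MINUTES_PER_DAY + base_minute
            t += rng_sched.normal(0.0, sched.meal_time_jitter_sd)
            t = float(np.round(np.clip(t, day * MINUTES_PER_DAY + sched.fingerstick_lead_min + 1,
                                       (day + 1) * MINUTES_PER_DAY - 1)))
            factor = float(np.exp(rng_sched.normal(0.0, sched.meal_size_jitter_sd)))
            comp = _jitter_composition(MEAL_TEMPLATES[name], factor)
            meals.append(MealEvent(t, comp))
            dose = comp.digestible_carb_g / 10.0 * sched.iu_per_10g_carb
            dose *= 1.0 + rng_sched.uniform(-sched.bolus_jitter, sched.bolus_jitter)
            dose = max(1.0, round(dose * 2.0) / 2.0)  # half-unit pen resolution
            insulins.append(
                InsulinEvent(t, dose, sched.bolus_product, "bolus", sched.bolus_t_max_i)
            )
            fs_times.append(t - sched.fingerstick_lead_min)
        if sched.basal_dose_iu > 0:
            insulins.append(
                InsulinEvent(
                    day * MINUTES_PER_DAY + sched.basal_minute,
                    sched.basal_dose_iu,
                    sched.basal_product,
                    "basal",
                    sched.basal_t_max_i,
                )
            )

    cgms_times = np.arange(0.0, duration, sched.cgms_cadence_min)
    fs_times_arr = np.array(sorted(fs_times))
    record_times = np.unique(np.concatenate([cgms_times, fs_times_arr]))

    params_true = spec.true_params()
    G_ss, I_ss = steady_state(params_true)
    skeleton = PatientLog(
        patient_id=f"virtual-{spec.seed}",
        body_weight_kg=spec.body_weight_kg,
        meals=meals,
        insulins=insulins,
        measurements=[],
        duration=duration,
    )
    truth = simulate(
        skeleton,
        params_true,
        profile=spec.true_profile(),
        restart_at_fingersticks=False,
        record_times=record_times,
        G0=G_ss,
        I0=I_ss,
    )
    truth_at = dict(zip(truth["t_min"], truth["G_mmol_l"]))

    true_cgms = np.array([truth_at[t] for t in cgms_times])
    rel_err = _cgms_noise(rng_cgms, cgms_times, spec.noise)
    cgms_values = np.maximum(true_cgms * (1.0 + rel_err), 0.5)

    measurements = [
        GlucoseMeasurement(float(t), float(v), "cgms")
        for t, v in zip(cgms_times, cgms_values)
    ]
    for t in fs_times_arr:
        true_v = truth_at[float(t)]
        noisy = true_v * (1.0 + rng_fs.normal(0.0, spec.noise.fingerstick_cv))
        measurements.append(GlucoseMeasurement(float(t), max(float(noisy), 0.5), "fingerstick"))

    log = PatientLog(
        patient_id=skeleton.patient_id,
        body_weight_kg=spec.body_weight_kg,
        meals=meals,
        insulins=insulins,
        measurements=measurements,
        duration=duration,
    )
    truth_grid = truth[truth["t_min"].isin(cgms_times)].reset_index(drop=True)
    return log, truth_grid
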