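"""Patient lifestyle logs: meals, insulin administrations and glucose measurements.

The data model mirrors what an insulin-treated outpatient can realistically
log on a phone: timestamped meals decomposed into five nutrient classes
(monosaccharides, starch portions with a glycemic index, lipids, proteins,
fibers), subcutaneous insulin doses identified by product, continuous
glucose monitor (CGMS) readings at a ~5-minute cadence, occasional
fingerstick self-measurements, and the patient's body weight.

All times are minutes since the start of the log (integers in practice);
``day_phase`` records the minute-of-day at log start so diurnal parameter
profiles can be anchored to clock time.  Glucose is stored in mmol/l;
mg/dl input is converted with the standard 18.016 (mg/dl)/(mmol/l) factor.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MG_DL_PER_MMOL_L",
    "MINUTES_PER_DAY",
    "DEFAULT_PRODUCT_REGISTRY",
    "NutrientComposition",
    "MealEvent",
    "InsulinEvent",
    "GlucoseMeasurement",
    "PatientLog",
    "read_log",
    "write_log",
    "slice_window",
]

#: Conversion factor between the two clinical glucose units.
MG_DL_PER_MMOL_L = 18.016

MINUTES_PER_DAY = 1440

#: Shipped insulin product registry: product -> (kind, time-to-maximum
#: absorption t_max_I in minutes).  Basal (long-acting) products are handled
#: exactly like boluses with a long t_max_I.
DEFAULT_PRODUCT_REGISTRY: dict[str, tuple[str, float]] = {
    "rapid_analog": ("bolus", 55.0),
    "regular": ("bolus", 90.0),
    "nph": ("basal", 300.0),
    "long_analog": ("basal", 600.0),
}


@dataclass
class NutrientComposition:
    """Nutrient content of one meal.

    ``starch_portions`` is a list of ``(mass_g, glycemic_index)`` pairs so a
    mixed dish can contain starches digested at different rates; the
    glycemic index acts as a relative hydrolysis-rate factor (1.0 = the
    reference starch).
    """

    monosaccharide_g: float = 0.0
    starch_portions: list[tuple[float, float]] = field(default_factory=list)
    lipid_g: float = 0.0
    protein_g: float = 0.0
    fiber_g: float = 0.0

    def __post_init__(self) -> None:
        for name in ("monosaccharide_g", "lipid_g", "protein_g", "fiber_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.starch_portions = [(float(m), float(gi)) for m, gi in self.starch_portions]
        for m, gi in self.starch_portions:
            if m < 0:
                raise ValueError("starch mass must be >= 0")
            if gi <= 0:
                raise ValueError("glycemic index must be > 0")

    @property
    def starch_g(self) -> float:
        return sum(m for m, _ in self.starch_portions)

    @property
    def digestible_carb_g(self) -> float:
        """Total carbohydrate that can appear as plasma glucose (g)."""
        return self.monosaccharide_g + self.starch_g

    def __add__(self, other: "NutrientComposition") -> "NutrientComposition":
        return NutrientComposition(
            self.monosaccharide_g + other.monosaccharide_g,
            list(self.starch_portions) + list(other.starch_portions),
            self.lipid_g + other.lipid_g,
            self.protein_g + other.protein_g,
            self.fiber_g + other.fiber_g,
        )


@dataclass
class MealEvent:
    time: float
    composition: NutrientComposition

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("meal time must be >= 0")


@dataclass
class InsulinEvent:
    time: float
    dose_iu: float
    product: str
    kind: str  # "bolus" | "basal"
    t_max_i: float  # minutes

    def __post_init__(self) -> None:
        if self.dose_iu <= 0:
            raise ValueError("insulin dose must be > 0")
        if self.t_max_i <= 0:
            raise ValueError("t_max_i must be > 0")
        if self.kind not in ("bolus", "basal"):
            raise ValueError(f"unknown insulin kind {self.kind!r}")


@dataclass
class GlucoseMeasurement:
    time: float
    value_mmol_l: float
    source: str  # "cgms" | "fingerstick"

    def __post_init__(self) -> None:
        if self.value_mmol_l <= 0:
            raise ValueError("glucose value must be > 0")
        if self.source not in ("cgms", "fingerstick"):
            raise ValueError(f"unknown measurement source {self.source!r}")


@dataclass
class PatientLog:
    """A time-ordered lifestyle log for one patient."""

    patient_id: str
    body_weight_kg: float
    meals: list[MealEvent] = field(default_factory=list)
    insulins: list[InsulinEvent] = field(default_factory=list)
    measurements: list[GlucoseMeasurement] = field(default_factory=list)
    duration: float = 0.0
    day_phase: float = 0.0  # minute-of-day at t = 0

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be > 0")
        self.meals = sorted(self.meals, key=lambda e: e.time)
        self.insulins = sorted(self.insulins, key=lambda e: e.time)
        self.measurements = sorted(self.measurements, key=lambda e: e.time)
        times = [e.time for e in self.meals + self.insulins + self.measurements]
        if times:
            if min(times) < 0:
                raise ValueError("event times must be >= 0")
            self.duration = max(self.duration, max(times))
        if not 0 <= self.day_phase < MINUTES_PER_DAY:
            raise ValueError("day_phase must lie in [0, 1440)")
        cg = self.cgms_times()
        if cg.size > 1 and not np.all(np.diff(cg) > 0):
            raise ValueError("CGMS series must be strictly increasing in time")

    # -- convenience accessors -------------------------------------------------

    def cgms(self) -> list[GlucoseMeasurement]:
        return [m for m in self.measurements if m.source == "cgms"]

    def fingersticks(self) -> list[GlucoseMeasurement]:
        return [m for m in self.measurements if m.source == "fingerstick"]

    def cgms_times(self) -> np.ndarray:
        return np.array([m.time for m in self.cgms()], dtype=float)

    def cgms_values(self) -> np.ndarray:
        return np.array([m.value_mmol_l for m in self.cgms()], dtype=float)

    def minute_of_day(self, t: float | np.ndarray) -> np.ndarray:
        return np.mod(np.asarray(t, dtype=float) + self.day_phase, MINUTES_PER_DAY)

    @property
    def n_days(self) -> float:
        return self.duration / MINUTES_PER_DAY

    def first_measurement_value(self) -> float | None:
        if not self.measurements:
            return None
        return self.measurements[0].value_mmol_l


# -- serialization -------------------------------------------------------------

_CSV_COLUMNS = [
    "time",
    "type",
    "mono_g",
    "starch_g",
    "gi",
    "lipid_g",
    "protein_g",
    "fiber_g",
    "dose_iu",
    "product",
    "value_mmol_l",
    "value_mg_dl",
    "weight_kg",
]


def _resolve_product(
    product: str,
    registry: dict[str, tuple[str, float]],
    default_t_max_i: float | None,
) -> tuple[str, float]:
    if product in registry:
        return registry[product]
    if default_t_max_i is not None:
        return ("bolus", float(default_t_max_i))
    raise ValueError(
        f"unknown insulin product {product!r}; add it to the registry or pass "
        "default_t_max_i"
    )


def _log_to_rows(log: PatientLog) -> list[dict]:
    rows: list[dict] = [{"time": 0, "type": "weight", "weight_kg": log.body_weight_kg}]
    for meal in log.meals:
        c = meal.composition
        if c.starch_portions:
            for i, (mass, gi) in enumerate(c.starch_portions):
                row = {"time": meal.time, "type": "meal", "starch_g": mass, "gi": gi}
                if i == 0:
                    row.update(
                        mono_g=c.monosaccharide_g,
                        lipid_g=c.lipid_g,
                        protein_g=c.protein_g,
                        fiber_g=c.fiber_g,
                    )
                else:
                    row.update(mono_g=0.0, lipid_g=0.0, protein_g=0.0, fiber_g=0.0)
                rows.append(row)
        else:
            rows.append(
                {
                    "time": meal.time,
                    "type": "meal",
                    "mono_g": c.monosaccharide_g,
                    "lipid_g": c.lipid_g,
                    "protein_g": c.protein_g,
                    "fiber_g": c.fiber_g,
                }
            )
    for ins in log.insulins:
        rows.append(
            {
                "time": ins.time,
                "type": "insulin",
                "dose_iu": ins.dose_iu,
                "product": ins.product,
            }
        )
    for m in log.measurements:
        rows.append({"time": m.time, "type": m.source, "value_mmol_l": m.value_mmol_l})
    rows.sort(key=lambda r: r["time"])
    return rows


def _rows_to_log(
    rows: pd.DataFrame,
    patient_id: str,
    duration: float | None,
    day_phase: float,
    registry: dict[str, tuple[str, float]],
    default_t_max_i: float | None,
) -> PatientLog:
    if not rows["time"].is_monotonic_increasing:
        warnings.warn("log rows were not sorted by time; sorting", stacklevel=3)
        rows = rows.sort_values("time", kind="stable")

    weight_rows = rows[rows["type"] == "weight"]
    if weight_rows.empty or weight_rows["weight_kg"].isna().all():
        raise ValueError("log contains no body weight record")
    body_weight = float(weight_rows["weight_kg"].dropna().iloc[0])

    meals: dict[float, NutrientComposition] = {}
    insulins: list[InsulinEvent] = []
    measurements: list[GlucoseMeasurement] = []
    for _, row in rows.iterrows():
        kind = row["type"]
        t = float(row["time"])
        if kind == "weight":
            continue
        if kind == "meal":
            portions = []
            starch = row.get("starch_g")
            if pd.notna(starch) and float(starch) > 0:
                gi = row.get("gi")
                portions = [(float(starch), float(gi) if pd.notna(gi) else 1.0)]
            def num(col: str) -> float:
                v = row.get(col)
                return float(v) if pd.notna(v) else 0.0

            comp = NutrientComposition(
                monosaccharide_g=num("mono_g"),
                starch_portions=portions,
                lipid_g=num("lipid_g"),
                protein_g=num("protein_g"),
                fiber_g=num("fiber_g"),
            )
            # rows at the same timestamp describe portions of one meal
            meals[t] = meals[t] + comp if t in meals else comp
        elif kind == "insulin":
            product = str(row["product"])
            pkind, tmax = _resolve_product(product, registry, default_t_max_i)
            insulins.append(InsulinEvent(t, float(row["dose_iu"]), product, pkind, tmax))
        elif kind in ("cgms", "fingerstick"):
            value = row.get("value_mmol_l")
            if pd.isna(value):
                value = float(row["value_mg_dl"]) / MG_DL_PER_MMOL_L
            measurements.append(GlucoseMeasurement(t, float(value), kind))
        else:
            raise ValueError(f"unknown log row type {kind!r}")

    log = PatientLog(
        patient_id=patient_id,
        body_weight_kg=body_weight,
        meals=[MealEvent(t, c) for t, c in sorted(meals.items())],
        insulins=insulins,
        measurements=measurements,
        duration=duration if duration is not None else 0.0,
        day_phase=day_phase,
    )
    return log


def read_log(
    path: str | Path,
    dialect: str | None = None,
    *,
    registry: dict[str, tuple[str, float]] | None = None,
    default_t_max_i: float | None = None,
) -> PatientLog:
    """Read a lifestyle log from the documented CSV or JSON schema.

    The dialect is inferred from the file extension unless given.  Glucose
    rows may carry either a ``value_mmol_l`` or a ``value_mg_dl`` column.
    Unknown insulin products are an error unless ``default_t_max_i``
    supplies a fallback time-to-maximum absorption.
    """
    path = Path(path)
    registry = registry if registry is not None else DEFAULT_PRODUCT_REGISTRY
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"

    if dialect == "json":
        payload = json.loads(path.read_text())
        meta = payload.get("meta", {})
        rows = pd.DataFrame(payload["events"], columns=_CSV_COLUMNS)
    elif dialect == "csv":
        meta = {}
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
        rows = pd.read_csv(path, comment="#", float_precision="round_trip")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for col in _CSV_COLUMNS:
        if col not in rows.columns:
            rows[col] = np.nan
    duration = float(meta["duration"]) if "duration" in meta else None
    return _rows_to_log(
        rows,
        patient_id=str(meta.get("patient_id", path.stem)),
        duration=duration,
        day_phase=float(meta.get("day_phase", 0.0)),
        registry=registry,
        default_t_max_i=default_t_max_i,
    )


def write_log(log: PatientLog, path: str | Path, dialect: str | None = None) -> None:
    """Write a log in the same schema that :func:`read_log` accepts."""
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    rows = _log_to_rows(log)
    meta = {
        "patient_id": log.patient_id,
        "duration": log.duration,
        "day_phase": log.day_phase,
    }
    if dialect == "json":
        path.write_text(json.dumps({"meta": meta, "events": rows}, indent=1))
    elif dialect == "csv":
        frame = pd.DataFrame(rows, columns=_CSV_COLUMNS)
        with path.open("w") as fh:
            for key, value in meta.items():
                fh.write(f"# {key}={value}\n")
            # %.17g keeps the round trip bit-exact for doubles
            frame.to_csv(fh, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# -- window slicing ------------------------------------------------------------


def _shift_event(event, offset: float):
    out = dataclasses.replace(event)
    out.time = event.time - offset
    return out


def slice_window(log: PatientLog, start: float, width: float) -> PatientLog:
    """Half-open window ``[start, start + width)`` of a log, times re-based to 0.

    ``day_phase`` is advanced so minute-of-day is preserved, which keeps
    diurnal profiles consistent across slices.  An empty window is a valid
    empty log.
    """
    if start < 0 or width < 0:
        raise ValueError("start and width must be >= 0")
    if start + width > log.duration:
        raise ValueError("window exceeds the log duration")

    def in_window(t: float) -> bool:
        return start <= t < start + width

    return PatientLog(
        patient_id=log.patient_id,
        body_weight_kg=log.body_weight_kg,
        meals=[_shift_event(e, start) for e in log.meals if in_window(e.time)],
        insulins=[_shift_event(e, start) for e in log.insulins if in_window(e.time)],
        measurements=[
            _shift_event(m, start) for m in log.measurements if in_window(m.time)
        ],
        duration=width,
        day_phase=float((log.day_phase + start) % MINUTES_PER_DAY),
    )
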