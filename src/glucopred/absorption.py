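"""Two-compartment (stomach + intestine) meal digestion model.

Each nutrient class entering the stomach is emptied into the intestine at a
shared first-order rate that is slowed by the lipid, protein and fiber mass
currently in the stomach.  Starch is hydrolysed to monosaccharide in the
intestine at a rate proportional to its glycemic index; intestinal
monosaccharide is absorbed into plasma at a first-order rate, producing the
appearance rate (g/min) that drives the glucose balance of the glycemia
model.  Lipids, proteins and fibers retard gastric emptying but contribute
no glucose.

Mass balance:  stomach + intestine + cumulative absorbed carbohydrate
equals the total ingested digestible carbohydrate at all times.

The model's structure (two compartments, five nutrient classes, glycemic
index as a relative hydrolysis rate, support for overlapping meals) is
fixed; the rate constants are population-level defaults chosen to give
physiologically plausible 30-90 min appearance peaks, and are never trained
per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lifestyle_log import MealEvent

__all__ = [
    "GLUCOSE_MOLAR_MASS_G_PER_MOL",
    "AbsorptionParams",
    "AbsorptionState",
    "add_meal",
    "absorption_rate",
    "glucose_input_rate",
]

#: Molar mass of glucose, used to convert g/min to mmol/min.
GLUCOSE_MOLAR_MASS_G_PER_MOL = 180.16


@dataclass(frozen=True)
class AbsorptionParams:
    """Digestion rate constants (all 1/min) and emptying retardation
    coefficients (dimensionless, per gram of stomach content)."""

    k_ge: float = 0.028  # basal gastric emptying rate
    k_hyd_ref: float = 0.023  # starch hydrolysis rate at glycemic index 1
    k_abs: float = 0.023  # intestinal monosaccharide absorption rate
    c_lipid: float = 0.02
    c_protein: float = 0.02
    c_fiber: float = 0.05

    def __post_init__(self) -> None:
        for name in ("k_ge", "k_hyd_ref", "k_abs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("c_lipid", "c_protein", "c_fiber"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class AbsorptionState:
    """Masses (g) in the two digestion compartments.

    Starch is tracked in per-glycemic-index pools so overlapping meals with
    different absorption characteristics evolve independently;
    ``absorbed_g`` accumulates carbohydrate that has crossed the intestine
    wall, closing the mass balance.
    """

    stomach_mono: float = 0.0
    stomach_lipid: float = 0.0
    stomach_protein: float = 0.0
    stomach_fiber: float = 0.0
    intestine_mono: float = 0.0
    absorbed_g: float = 0.0
    starch_gi: np.ndarray = field(default_factory=lambda: np.zeros(0))
    stomach_starch: np.ndarray = field(default_factory=lambda: np.zeros(0))
    intestine_starch: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def total_carb_g(self) -> float:
        """Digestible carbohydrate currently in transit plus already absorbed."""
        return (
            self.stomach_mono
            + self.intestine_mono
            + float(self.stomach_starch.sum())
            + float(self.intestine_starch.sum())
            + self.absorbed_g
        )

    def copy(self) -> "AbsorptionState":
        return replace(
            self,
            starch_gi=self.starch_gi.copy(),
            stomach_starch=self.stomach_starch.copy(),
            intestine_starch=self.intestine_starch.copy(),
        )


def add_meal(state: AbsorptionState, meal: MealEvent) -> AbsorptionState:
    """Add a meal's nutrients to the stomach; the intestine is untouched.

    Meals arriving while earlier absorption is still in progress simply
    superpose: masses add, and starch portions with a glycemic index already
    present merge into that pool.
    """
    comp = meal.composition
    out = state.copy()
    out.stomach_mono += comp.monosaccharide_g
    out.stomach_lipid += comp.lipid_g
    out.stomach_protein += comp.protein_g
    out.stomach_fiber += comp.fiber_g
    for mass, gi in comp.starch_portions:
        if mass == 0:
            continue
        matches = np.nonzero(out.starch_gi == gi)[0]
        if matches.size:
            out.stomach_starch[matches[0]] += mass
        else:
            out.starch_gi = np.append(out.starch_gi, gi)
            out.stomach_starch = np.append(out.stomach_starch, mass)
            out.intestine_starch = np.append(out.intestine_starch, 0.0)
    return out


def absorption_rate(
    state: AbsorptionState, params: AbsorptionParams
) -> tuple[AbsorptionState, float]:
    """Time derivative of the digestion state and the plasma appearance rate.

    Returns ``(d_state_dt, appearance_g_per_min)`` where ``d_state_dt`` is
    an :class:`AbsorptionState` holding derivatives (g/min) in each field.
    """
    masses = [
        state.stomach_mono,
        state.stomach_lipid,
        state.stomach_protein,
        state.stomach_fiber,
        state.intestine_mono,
    ]
    if min(masses, default=0.0) < -1e-9 or (
        state.stomach_starch.size
        and min(state.stomach_starch.min(), state.intestine_starch.min()) < -1e-9
    ):
        raise ValueError("negative compartment mass (integrator fault)")

    k_empty = params.k_ge / (
        1.0
        + params.c_lipid * state.stomach_lipid
        + params.c_protein * state.stomach_protein
        + params.c_fiber * state.stomach_fiber
    )
    hyd = params.k_hyd_ref * state.starch_gi * state.intestine_starch
    appearance = params.k_abs * state.intestine_mono
    d = AbsorptionState(
        stomach_mono=-k_empty * state.stomach_mono,
        stomach_lipid=-k_empty * state.stomach_lipid,
        stomach_protein=-k_empty * state.stomach_protein,
        stomach_fiber=-k_empty * state.stomach_fiber,
        intestine_mono=k_empty * state.stomach_mono + float(hyd.sum()) - appearance,
        absorbed_g=appearance,
        starch_gi=state.starch_gi.copy(),
        stomach_starch=-k_empty * state.stomach_starch,
        intestine_starch=k_empty * state.stomach_starch - hyd,
    )
    return d, appearance


def glucose_input_rate(
    appearance_g_per_min: float | np.ndarray, v_g: float, body_weight_kg: float
) -> float | np.ndarray:
    """Convert a plasma appearance rate (g/min) into a glucose concentration
    rate (mmol/l/min) in the glucose distribution volume ``v_g`` (l/kgBW)."""
    if v_g <= 0 or body_weight_kg <= 0:
        raise ValueError("V_G and body weight must be > 0")
    if np.any(np.asarray(appearance_g_per_min) < 0):
        raise ValueError("appearance rate must be >= 0")
    mmol_per_min = appearance_g_per_min / GLUCOSE_MOLAR_MASS_G_PER_MOL * 1000.0
    return mmol_per_min / (v_g * body_weight_kg)


# -- flat-vector form used by the integrator ----------------------------------

_N_SCALAR = 6  # mono, lipid, protein, fiber, intestine_mono, absorbed


def pack_state(state: AbsorptionState) -> tuple[np.ndarray, np.ndarray]:
    """Flatten to ``(y, gi)`` with layout
    ``[mono, lipid, protein, fiber, intestine_mono, absorbed, stomach_starch..., intestine_starch...]``."""
    y = np.concatenate(
        [
            [
                state.stomach_mono,
                state.stomach_lipid,
                state.stomach_protein,
                state.stomach_fiber,
                state.intestine_mono,
                state.absorbed_g,
            ],
            state.stomach_starch,
            state.intestine_starch,
        ]
    )
    return y, state.starch_gi.copy()


def unpack_state(y: np.ndarray, gi: np.ndarray) -> AbsorptionState:
    n = gi.size
    return AbsorptionState(
        stomach_mono=float(y[0]),
        stomach_lipid=float(y[1]),
        stomach_protein=float(y[2]),
        stomach_fiber=float(y[3]),
        intestine_mono=float(y[4]),
        absorbed_g=float(y[5]),
        starch_gi=gi.copy(),
        stomach_starch=y[_N_SCALAR : _N_SCALAR + n].copy(),
        intestine_starch=y[_N_SCALAR + n :].copy(),
    )


def rhs_flat(
    y: np.ndarray, gi: np.ndarray, params: AbsorptionParams
) -> tuple[np.ndarray, float]:
    """Derivative of the flat state vector and the appearance rate (g/min)."""
    n = gi.size
    k_empty = params.k_ge / (
        1.0 + params.c_lipid * y[1] + params.c_protein * y[2] + params.c_fiber * y[3]
    )
    sto_starch = y[_N_SCALAR : _N_SCALAR + n]
    int_starch = y[_N_SCALAR + n :]
    hyd = params.k_hyd_ref * gi * int_starch
    appearance = params.k_abs * y[4]
    dy = np.empty_like(y)
    dy[0] = -k_empty * y[0]
    dy[1] = -k_empty * y[1]
    dy[2] = -k_empty * y[2]
    dy[3] = -k_empty * y[3]
    dy[4] = k_empty * y[0] + hyd.sum() - appearance
    dy[5] = appearance
    dy[_N_SCALAR : _N_SCALAR + n] = -k_empty * sto_starch
    dy[_N_SCALAR + n :] = k_empty * sto_starch - hyd
    return dy, appearance
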