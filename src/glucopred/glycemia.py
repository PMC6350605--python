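"""Delay-differential glucose-insulin control model with subcutaneous depots.

State variables and equations (minutes, mmol/l, pM = pmol/l):

    dG/dt  = -K_xgi * G * I + T_GH / V_G + delta_a_monosac(t)
    dI/dt  = -K_xi * I + (T_iGmax / V_I) * f(G(t - tau_G))
             + sum_depots S2 / (V_I * t_max_I)
    dS1/dt = -S1 / t_max_I          (per subcutaneous administration)
    dS2/dt = (S1 - S2) / t_max_I

with the sigmoidal endogenous release fraction

    f(G) = (G/G*)^gamma / (1 + (G/G*)^gamma),

so f(G*) = 1/2 and gamma sets how steeply the pancreas responds.  Insulin
injections add dose * 6000 / body_weight pmol/kgBW to a fresh S1 depot
(1 IU = 6 nmol); each administration keeps its own depot pair because the
time-to-maximum absorption t_max_I is product dependent.  delta_a_monosac
is the meal-derived glucose appearance computed by the digestion model.

Default parameter values are population-level optimized literature values;
personalization multiplies a subset of them (see ``identification``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lifestyle_log import GlucoseMeasurement, InsulinEvent, PatientLog

__all__ = [
    "PARAM_NAMES",
    "IU_TO_PMOL",
    "GlycemiaParams",
    "DepotPair",
    "ModelState",
    "StateDerivative",
    "endogenous_release_fraction",
    "steady_state",
    "steady_state_batch",
    "inject_insulin",
    "derivatives",
    "restart",
    "simulate",
]

#: The nine trainable model parameters, in canonical order.
PARAM_NAMES = (
    "K_xgi",
    "T_GH",
    "V_G",
    "K_xi",
    "T_iGmax",
    "V_I",
    "tau_G",
    "G_star",
    "gamma",
)

#: 1 IU of insulin = 6 nmol = 6000 pmol.
IU_TO_PMOL = 6000.0

#: Depot pairs whose total content falls below this (pmol/kgBW) are dropped.
DEPOT_EPSILON = 1e-9


@dataclass(frozen=True)
class GlycemiaParams:
    """Glucose control model parameters (population-level defaults)."""

    K_xgi: float = 3.11e-5  # glucose uptake by insulin-dependent tissues, 1/(min*pM)
    T_GH: float = 0.003  # net hepatic glucose balance, mmol/(min*kgBW)
    V_G: float = 0.187  # glucose distribution volume, l/kgBW
    K_xi: float = 1.211e-2  # first-order insulin disappearance, 1/min
    T_iGmax: float = 0.1  # maximal second-phase insulin release, pmol/(min*kgBW)
    V_I: float = 0.236  # insulin distribution volume, l/kgBW
    tau_G: float = 24.0  # pancreatic response delay, min
    G_star: float = 9.0  # glycaemia of half-maximal insulin release, mmol/l
    gamma: float = 3.205  # progressivity of the pancreatic response
    body_weight_kg: float = 70.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES + ("body_weight_kg",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gamma <= 1:
            raise ValueError("gamma must be > 1")

    def with_multipliers(self, multipliers: dict[str, float]) -> "GlycemiaParams":
        """Scale named parameters by dimensionless multipliers."""
        unknown = set(multipliers) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        return replace(
            self, **{k: getattr(self, k) * m for k, m in multipliers.items()}
        )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


def endogenous_release_fraction(
    G: float | np.ndarray, G_star: float = 9.0, gamma: float = 3.205
) -> float | np.ndarray:
    """Fraction of the maximal second-phase insulin release at glycaemia ``G``.

    Strictly increasing, 0 at G = 0, 1/2 at G = G*, -> 1 as G -> infinity.
    """
    x = np.maximum(np.asarray(G, dtype=float), 0.0) / G_star
    z = np.power(x, gamma)
    out = z / (1.0 + z)
    return float(out) if np.isscalar(G) or np.ndim(G) == 0 else out


def steady_state_batch(params: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Basal (no meal, no injection) equilibrium per candidate, vectorized.

    At equilibrium I = (T_iGmax / (K_xi V_I)) f(G) and
    T_GH / V_G = K_xgi G I; the left side is constant while the right side
    is strictly increasing in G, so the root is unique and bracketed
    bisection converges unconditionally.
    """
    K_xgi = np.asarray(params["K_xgi"], dtype=float)
    target = params["T_GH"] / params["V_G"]
    c_i = params["T_iGmax"] / (params["K_xi"] * params["V_I"])
    G_star = params["G_star"]
    gamma = params["gamma"]

    def uptake(G: np.ndarray) -> np.ndarray:
        z = np.power(G / G_star, gamma)
        return K_xgi * G * c_i * z / (1.0 + z)

    lo = np.full_like(K_xgi, 1e-9)
    hi = np.full_like(K_xgi, 1e9)
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        high = uptake(mid) > target
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    G_ss = 0.5 * (lo + hi)
    z = np.power(G_ss / G_star, gamma)
    I_ss = c_i * z / (1.0 + z)
    return G_ss, I_ss


def steady_state(params: GlycemiaParams) -> tuple[float, float]:
    """Basal equilibrium (G_ss mmol/l, I_ss pM) of the model."""
    batch = {name: np.array([getattr(params, name)]) for name in PARAM_NAMES}
    G_ss, I_ss = steady_state_batch(batch)
    return float(G_ss[0]), float(I_ss[0])


# -- scalar model state (reference implementation) ----------------------------


@dataclass
class DepotPair:
    """Subcutaneous depot chain of one administration (pmol/kgBW)."""

    S1: float
    S2: float
    t_max_i: float

    def __post_init__(self) -> None:
        if self.S1 < 0 or self.S2 < 0:
            raise ValueError("depot masses must be >= 0")


@dataclass
class ModelState:
    """Instantaneous model state with the glucose history needed for the delay."""

    t: float
    G: float
    I: float
    depots: list[DepotPair] = field(default_factory=list)
    # history of (time, G) pairs covering at least [t - tau_G, t]
    G_history: list[tuple[float, float]] = field(default_factory=list)

    def delayed_glucose(self, when: float) -> float:
        """Linearly interpolated G at an earlier time; constant before the
        first recorded point (pre-history)."""
        hist = self.G_history or [(self.t, self.G)]
        times = np.array([p[0] for p in hist])
        values = np.array([p[1] for p in hist])
        return float(np.interp(when, times, values))


@dataclass
class StateDerivative:
    dG: float
    dI: float
    depots: list[tuple[float, float]]  # (dS1, dS2) per administration


def inject_insulin(
    state: ModelState, event: InsulinEvent, body_weight_kg: float
) -> ModelState:
    """Append a fresh depot pair for one administration; existing depots are
    untouched (administrations superpose)."""
    if event.dose_iu <= 0:
        raise ValueError("insulin dose must be > 0")
    if abs(event.time - state.t) > 1e-9:
        raise ValueError("injection time must equal the state time")
    depots = [replace(d) for d in state.depots]
    depots.append(
        DepotPair(event.dose_iu * IU_TO_PMOL / body_weight_kg, 0.0, event.t_max_i)
    )
    return replace(state, depots=depots, G_history=list(state.G_history))


def derivatives(
    state: ModelState, params: GlycemiaParams, delta_a_monosac: float = 0.0
) -> StateDerivative:
    """Model right-hand side at the state's current time."""
    G_del = state.delayed_glucose(state.t - params.tau_G)
    f_del = endogenous_release_fraction(G_del, params.G_star, params.gamma)
    release = sum(d.S2 / d.t_max_i for d in state.depots)
    dG = -params.K_xgi * state.G * state.I + params.T_GH / params.V_G + delta_a_monosac
    dI = -params.K_xi * state.I + (params.T_iGmax / params.V_I) * f_del + release / params.V_I
    depot_d = [(-d.S1 / d.t_max_i, (d.S1 - d.S2) / d.t_max_i) for d in state.depots]
    return StateDerivative(dG=dG, dI=dI, depots=depot_d)


def restart(state: ModelState, measurement: GlucoseMeasurement) -> ModelState:
    """Reset glucose to a fingerstick value; insulin and depots are kept.

    The glucose history is re-seeded to the measured value so the delayed
    pancreatic response also sees the corrected level.
    """
    if measurement.source != "fingerstick":
        raise ValueError("model restarts anchor on fingerstick measurements")
    if abs(measurement.time - state.t) > 1e-9:
        raise ValueError("measurement time must equal the state time")
    if measurement.value_mmol_l <= 0:
        raise ValueError("glucose value must be > 0")
    return replace(
        state,
        G=measurement.value_mmol_l,
        depots=[replace(d) for d in state.depots],
        G_history=[(state.t - 1.0, measurement.value_mmol_l), (state.t, measurement.value_mmol_l)],
    )


# -- high-level simulation -----------------------------------------------------


def simulate(
    log: PatientLog,
    params: GlycemiaParams,
    absorption_params=None,
    *,
    profile=None,
    restart_at_fingersticks: bool = True,
    step: float = 1.0,
    record_every: float | None = 5.0,
    record_times: np.ndarray | None = None,
    G0: float | None = None,
    I0: float | None = None,
) -> pd.DataFrame:
    """Simulate a full log window and return a trajectory DataFrame.

    Meals and insulin administrations are applied at their timestamps; if
    ``restart_at_fingersticks`` the predicted glucose is reset to each
    fingerstick value.  The initial glucose defaults to the log's first
    measurement (or the basal steady state for an unmeasured log) and the
    initial insulin to its steady-state value.  Columns: ``t_min``,
    ``G_mmol_l``, ``I_pM``.
    """
    from . import engine

    if record_times is None:
        record_times = np.arange(0.0, log.duration + 1e-9, record_every)
    prep = engine.prepare_window(
        log,
        absorption_params,
        step=step,
        restart=restart_at_fingersticks,
        record_times=np.asarray(record_times, dtype=float),
        G0=G0,
    )
    if prep.G0 is None:
        prep.G0 = steady_state(params)[0]
    batch = engine.params_to_batch(params)
    i0_arr = None if I0 is None else np.array([I0], dtype=float)
    out = engine.run_batch(prep, batch, profile=profile, I0=i0_arr, return_insulin=True)
    if not out["ok"].all():
        raise FloatingPointError(
            "simulation lost finiteness; offending parameters: "
            + ", ".join(f"{k}={v[0]:.4g}" for k, v in batch.items())
        )
    return pd.DataFrame(
        {"t_min": out["times"], "G_mmol_l": out["G"][0], "I_pM": out["I"][0]}
    )
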