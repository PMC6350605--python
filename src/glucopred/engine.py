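"""Fixed-step numerical core shared by simulation, training and evaluation.

The combined model is triangular: digestion (stomach/intestine masses) and
the subcutaneous insulin depots evolve independently of the glucose-insulin
pair, while glucose and insulin are driven by the digestion appearance rate
and the depot release rate.  The core therefore integrates in two passes on
one clock:

1. a shared pass (per log window, parameter-free) advances the digestion
   compartments and every injection's depot pair with classical RK4 at half
   the glycemia step, recording the monosaccharide appearance rate (g/min)
   and the depot release rate sum S2/t_max_I at every half-step node — i.e.
   exactly at the RK4 stage times of the second pass;
2. a batched pass advances (G, I) with RK4 for a whole matrix of candidate
   parameter vectors at once, reading the recorded inputs, interpolating
   the delayed glucose G(t - tau_G) from its own history with a cubic
   Hermite scheme (so the delay term does not degrade the integrator's
   fourth order), applying model restarts at fingerstick measurements, and
   sampling the trajectory at the requested output times.

Both passes apply meal and insulin events as discrete state updates at
their (grid-aligned) timestamps.  Evaluating hundreds of candidate
parameter vectors against one window costs one shared pass plus one
vectorized batched pass, which is what keeps grid search and the genetic
algorithm affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import absorption as ab
from .absorption import AbsorptionParams, AbsorptionState
from .glycemia import IU_TO_PMOL, PARAM_NAMES, GlycemiaParams, steady_state_batch
from .lifestyle_log import MINUTES_PER_DAY, PatientLog

__all__ = ["PreparedWindow", "prepare_window", "run_batch", "params_to_batch"]


@dataclass
class PreparedWindow:
    """Shared-pass results for one log window, reusable across candidates."""

    step: float
    n_steps: int
    body_weight_kg: float
    day_phase: float
    G0: float
    appearance_nodes: np.ndarray  # (2n+1,) g/min at half-step nodes
    depot_rate_nodes: np.ndarray  # (2n+1,) sum S2/t_max_I, pmol/kgBW/min
    record_idx: np.ndarray  # step indices where output is sampled
    record_times: np.ndarray
    restart_schedule: list[tuple[int, float]]  # (step index, fingerstick mmol/l)
    # diagnostics from the shared pass
    carb_ingested_g: float
    carb_balance_error_g: float
    insulin_injected_pmol_kg: float
    insulin_depot_residual_pmol_kg: float
    insulin_absorbed_pmol_kg: float


def _grid_index(t: float, step: float, what: str) -> int:
    idx = t / step
    r = round(idx)
    if abs(idx - r) > 1e-9:
        raise ValueError(f"{what} time {t} min does not align with the {step}-min grid")
    return int(r)


def prepare_window(
    log: PatientLog,
    absorption_params: AbsorptionParams | None = None,
    *,
    step: float = 1.0,
    restart: bool = True,
    record_times: np.ndarray | None = None,
    G0: float | None = None,
    initial_state: AbsorptionState | None = None,
) -> PreparedWindow:
    """Run the shared digestion + depot pass over a log window.

    ``record_times`` defaults to the log's CGMS timestamps (the points a
    prediction is scored on); ``G0`` defaults to the log's first glucose
    measurement.  Event and record times must align with the step grid —
    logs use integer minutes, so the default 1-min step always fits.
    """
    if absorption_params is None:
        absorption_params = AbsorptionParams()
    if step <= 0:
        raise ValueError("step must be > 0")
    duration = log.duration
    n_steps = _grid_index(duration, step, "window end")
    if n_steps == 0:
        raise ValueError("window has zero duration")
    h2 = step / 2.0
    n_half = 2 * n_steps

    meals_at: dict[int, list] = {}
    for meal in log.meals:
        meals_at.setdefault(_grid_index(meal.time, h2, "meal"), []).append(meal)
    depots_at: dict[int, list[tuple[float, float]]] = {}
    injected = 0.0
    for ins in log.insulins:
        s1 = ins.dose_iu * IU_TO_PMOL / log.body_weight_kg
        injected += s1
        depots_at.setdefault(_grid_index(ins.time, h2, "insulin"), []).append(
            (s1, ins.t_max_i)
        )

    # --- digestion compartments, RK4 at h/2, appearance recorded per node ----
    state = initial_state.copy() if initial_state is not None else AbsorptionState()
    y, gi = ab.pack_state(state)
    appearance = np.zeros(n_half + 1)
    balance_err = 0.0
    ingested = state.total_carb_g()
    carb_idx = [0, 4, 5]  # stomach mono, intestine mono, cumulative absorbed

    def carb_total(yv: np.ndarray) -> float:
        return float(yv[carb_idx].sum() + yv[ab._N_SCALAR :].sum())

    for node in range(n_half + 1):
        if node in meals_at:
            st = ab.unpack_state(y, gi)
            for meal in meals_at[node]:
                st = ab.add_meal(st, meal)
                ingested += meal.composition.digestible_carb_g
            y, gi = ab.pack_state(st)
        appearance[node] = absorption_params.k_abs * y[4]
        balance_err = max(balance_err, abs(carb_total(y) - ingested))
        if node == n_half:
            break
        k1, _ = ab.rhs_flat(y, gi, absorption_params)
        k2, _ = ab.rhs_flat(y + 0.5 * h2 * k1, gi, absorption_params)
        k3, _ = ab.rhs_flat(y + 0.5 * h2 * k2, gi, absorption_params)
        k4, _ = ab.rhs_flat(y + h2 * k3, gi, absorption_params)
        y = y + (h2 / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

    # --- insulin depots, RK4 at h/2, release rate recorded per node ----------
    # state: S1[], S2[] (pmol/kgBW) per administration, plus cumulative
    # plasma appearance for the mass balance.
    S1 = np.zeros(0)
    S2 = np.zeros(0)
    inv_tmax = np.zeros(0)
    absorbed_ins = 0.0
    depot_rate = np.zeros(n_half + 1)
    for node in range(n_half + 1):
        if node in depots_at:
            for s1_add, tmax in depots_at[node]:
                S1 = np.append(S1, s1_add)
                S2 = np.append(S2, 0.0)
                inv_tmax = np.append(inv_tmax, 1.0 / tmax)
        depot_rate[node] = float((S2 * inv_tmax).sum())
        if node == n_half:
            break
        # RK4 on dS1 = -S1/tmax, dS2 = (S1 - S2)/tmax, dA = sum S2/tmax
        a1, b1, r1 = -S1 * inv_tmax, (S1 - S2) * inv_tmax, (S2 * inv_tmax).sum()
        s1b, s2b = S1 + 0.5 * h2 * a1, S2 + 0.5 * h2 * b1
        a2, b2, r2 = -s1b * inv_tmax, (s1b - s2b) * inv_tmax, (s2b * inv_tmax).sum()
        s1c, s2c = S1 + 0.5 * h2 * a2, S2 + 0.5 * h2 * b2
        a3, b3, r3 = -s1c * inv_tmax, (s1c - s2c) * inv_tmax, (s2c * inv_tmax).sum()
        s1d, s2d = S1 + h2 * a3, S2 + h2 * b3
        a4, b4, r4 = -s1d * inv_tmax, (s1d - s2d) * inv_tmax, (s2d * inv_tmax).sum()
        S1 = S1 + (h2 / 6.0) * (a1 + 2 * a2 + 2 * a3 + a4)
        S2 = S2 + (h2 / 6.0) * (b1 + 2 * b2 + 2 * b3 + b4)
        absorbed_ins += (h2 / 6.0) * (r1 + 2 * r2 + 2 * r3 + r4)

    # --- bookkeeping ----------------------------------------------------------
    if record_times is None:
        record_times = log.cgms_times()
    record_times = np.asarray(record_times, dtype=float)
    record_idx = np.array(
        [_grid_index(t, step, "record") for t in record_times], dtype=int
    )
    if np.any(record_idx > n_steps):
        raise ValueError("record time outside the window")

    restart_schedule: list[tuple[int, float]] = []
    if restart:
        for m in log.fingersticks():
            restart_schedule.append((_grid_index(m.time, step, "fingerstick"), m.value_mmol_l))
        restart_schedule.sort()

    if G0 is None:
        G0 = log.first_measurement_value()

    return PreparedWindow(
        step=step,
        n_steps=n_steps,
        body_weight_kg=log.body_weight_kg,
        day_phase=log.day_phase,
        G0=G0 if G0 is None else float(G0),
        appearance_nodes=appearance,
        depot_rate_nodes=depot_rate,
        record_idx=record_idx,
        record_times=record_times,
        restart_schedule=restart_schedule,
        carb_ingested_g=ingested,
        carb_balance_error_g=balance_err,
        insulin_injected_pmol_kg=injected,
        insulin_depot_residual_pmol_kg=float(S1.sum() + S2.sum()),
        insulin_absorbed_pmol_kg=absorbed_ins,
    )


def params_to_batch(
    base: GlycemiaParams,
    names: tuple[str, ...] = (),
    multipliers: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Expand a base parameter set and a (P, k) multiplier matrix over the
    named parameters into per-name arrays of shape (P,)."""
    if multipliers is None:
        multipliers = np.ones((1, len(names)))
    multipliers = np.atleast_2d(np.asarray(multipliers, dtype=float))
    n_cand = multipliers.shape[0]
    if multipliers.shape[1] != len(names):
        raise ValueError("multiplier matrix width must match the number of names")
    batch = {name: np.full(n_cand, getattr(base, name)) for name in PARAM_NAMES}
    for j, name in enumerate(names):
        if name not in batch:
            raise KeyError(f"unknown parameter {name!r}")
        batch[name] = batch[name] * multipliers[:, j]
    return batch


def _release_fraction(x: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Stable (G/G*)^gamma / (1 + (G/G*)^gamma) with f(x<=0) = 0."""
    x = np.maximum(x, 0.0)
    z = np.power(x, gamma)
    return z / (1.0 + z)


def run_batch(
    prep: PreparedWindow,
    params: dict[str, np.ndarray],
    *,
    profile=None,
    G0: float | None = None,
    I0: np.ndarray | None = None,
    return_insulin: bool = False,
) -> dict:
    """Integrate the glucose-insulin pair for a batch of parameter vectors.

    ``params`` maps each of the nine model parameter names to a (P,) array
    (see :func:`params_to_batch`).  ``profile`` is an optional diurnal
    multiplier curve applied to its configured parameter(s) as a function of
    minute-of-day.  Returns a dict with ``G`` of shape (P, n_record), the
    candidate feasibility mask ``ok`` (False where the trajectory lost
    finiteness), and optionally ``I``.
    """
    h = prep.step
    n = prep.n_steps
    P = len(params["K_xgi"])

    K_xgi = params["K_xgi"]
    T_GH_VG = params["T_GH"] / params["V_G"]
    c_app = 1000.0 / (ab.GLUCOSE_MOLAR_MASS_G_PER_MOL * params["V_G"] * prep.body_weight_kg)
    K_xi = params["K_xi"]
    TiG_VI = params["T_iGmax"] / params["V_I"]
    inv_VI = 1.0 / params["V_I"]
    tau = params["tau_G"]
    G_star = params["G_star"]
    gamma = params["gamma"]
    if np.any(tau <= h):
        raise ValueError("tau_G must exceed the integration step")

    prof_names: tuple[str, ...] = ()
    prof_nodes = None
    if profile is not None:
        prof_names = tuple(profile.param_names)
        if "tau_G" in prof_names:
            raise ValueError("diurnal profiling of the delay tau_G is not supported")
        node_times = np.arange(2 * n + 1) * (h / 2.0)
        minutes = np.mod(node_times + prep.day_phase, MINUTES_PER_DAY)
        prof_nodes = profile.multipliers(minutes)

    g0 = prep.G0 if G0 is None else float(G0)
    if g0 is None:
        raise ValueError("no initial glucose value: log has no measurements and no G0 given")
    if I0 is None:
        _, I0 = steady_state_batch(params)
    I = np.array(I0, dtype=float) * np.ones(P)
    G = np.full(P, g0, dtype=float)

    restart_at = dict(prep.restart_schedule)
    if 0 in restart_at:
        G[:] = restart_at[0]

    # History layout: `pad` rows of constant pre-history are prepended so the
    # delayed lookup never needs a branch; row pad + i holds G at t = i*h.
    # d_left / d_right hold the RK4 end-point derivatives of each step, giving
    # the cubic Hermite interpolant its O(h^4) accuracy for the delay term.
    pad = int(np.ceil(float(tau.max()) / h)) + 1
    Ghist = np.empty((pad + n + 1, P))
    Ghist[: pad + 1] = G  # constant pre-history (post-restart value if any)
    d_left = np.zeros((pad + n, P))
    d_right = np.zeros((pad + n, P))
    Ihist = np.empty((n + 1, P)) if return_insulin else None
    if Ihist is not None:
        Ihist[0] = I

    app = prep.appearance_nodes
    R = prep.depot_rate_nodes

    # tau_G is constant during a run, so the fractional position of the
    # delayed sample inside its history interval is the same every step;
    # only the interval index advances.  Precompute the Hermite weights per
    # RK4 stage (stage times t, t+h/2, t+h).
    uniform_tau = float(tau.max() - tau.min()) == 0.0
    cand = np.arange(P)
    stage_lookup = []
    for offset in (0.0, 0.5, 1.0):
        sp = offset - tau / h + pad  # history coordinate at step i=0, (P,)
        idx = np.floor(sp).astype(int)
        th = sp - idx
        t2, t3 = th * th, th * th * th
        w = (
            2.0 * t3 - 3.0 * t2 + 1.0,
            h * (t3 - 2.0 * t2 + th),
            -2.0 * t3 + 3.0 * t2,
            h * (t3 - t2),
        )
        if uniform_tau:
            stage_lookup.append((int(idx[0]), tuple(float(x[0]) for x in w)))
        else:
            stage_lookup.append((idx, w))

    if uniform_tau:

        def delayed(i: int, stage: int) -> np.ndarray:
            idx0, (w0, w1, w2, w3) = stage_lookup[stage]
            j = idx0 + i
            return w0 * Ghist[j] + w1 * d_left[j] + w2 * Ghist[j + 1] + w3 * d_right[j]

    else:

        def delayed(i: int, stage: int) -> np.ndarray:
            idx0, (w0, w1, w2, w3) = stage_lookup[stage]
            j = idx0 + i
            return (
                w0 * Ghist[j, cand]
                + w1 * d_left[j, cand]
                + w2 * Ghist[j + 1, cand]
                + w3 * d_right[j, cand]
            )

    def stage_coeffs(node: int):
        if prof_nodes is None:
            return K_xgi, T_GH_VG, c_app, K_xi, TiG_VI, inv_VI, G_star, gamma
        p = prof_nodes[node]
        A, B, Ca, C, D, E, Gs, gm = (
            K_xgi, T_GH_VG, c_app, K_xi, TiG_VI, inv_VI, G_star, gamma,
        )
        for name in prof_names:
            if name == "K_xgi":
                A = A * p
            elif name == "T_GH":
                B = B * p
            elif name == "V_G":
                B, Ca = B / p, Ca / p
            elif name == "K_xi":
                C = C * p
            elif name == "T_iGmax":
                D = D * p
            elif name == "V_I":
                D, E = D / p, E / p
            elif name == "G_star":
                Gs = Gs * p
            elif name == "gamma":
                gm = gm * p
        return A, B, Ca, C, D, E, Gs, gm

    h6 = h / 6.0
    h5 = 0.5 * h
    with np.errstate(all="ignore"):
        for i in range(n):
            n0 = 2 * i
            n1 = n0 + 1
            n2 = n0 + 2
            c0 = stage_coeffs(n0)
            c1 = stage_coeffs(n1)
            c2 = stage_coeffs(n2)
            f0 = _release_fraction(delayed(i, 0) / c0[6], c0[7])
            f1 = _release_fraction(delayed(i, 1) / c1[6], c1[7])
            f2 = _release_fraction(delayed(i, 2) / c2[6], c2[7])

            # stage 1
            A, B, Ca, C, D, E, _, _ = c0
            kG1 = -A * G * I + B + Ca * app[n0]
            kI1 = -C * I + D * f0 + E * R[n0]
            Gs_, Is_ = G + h5 * kG1, I + h5 * kI1
            # stage 2
            A, B, Ca, C, D, E, _, _ = c1
            kG2 = -A * Gs_ * Is_ + B + Ca * app[n1]
            kI2 = -C * Is_ + D * f1 + E * R[n1]
            Gs_, Is_ = G + h5 * kG2, I + h5 * kI2
            # stage 3
            kG3 = -A * Gs_ * Is_ + B + Ca * app[n1]
            kI3 = -C * Is_ + D * f1 + E * R[n1]
            Gs_, Is_ = G + h * kG3, I + h * kI3
            # stage 4
            A, B, Ca, C, D, E, _, _ = c2
            kG4 = -A * Gs_ * Is_ + B + Ca * app[n2]
            kI4 = -C * Is_ + D * f2 + E * R[n2]

            d_left[pad + i] = kG1
            d_right[pad + i] = kG4
            G = G + h6 * (kG1 + 2.0 * (kG2 + kG3) + kG4)
            I = I + h6 * (kI1 + 2.0 * (kI2 + kI3) + kI4)
            Ghist[pad + i + 1] = G
            if Ihist is not None:
                Ihist[i + 1] = I

            value = restart_at.get(i + 1)
            if value is not None:
                # fingerstick restart: reset glucose only, re-seed its
                # history; insulin and the depots are left untouched
                G = np.full(P, value)
                lo = i + 1  # row pad+i+1 minus one full delay span
                Ghist[lo : pad + i + 2] = value
                d_left[lo : pad + i + 1] = 0.0
                d_right[lo : pad + i + 1] = 0.0

    G_rec = Ghist[pad + prep.record_idx].T.copy()
    ok = np.isfinite(G_rec).all(axis=1) & np.isfinite(I) & np.isfinite(G)
    out = {"G": G_rec, "ok": ok, "times": prep.record_times}
    if return_insulin:
        out["I"] = Ihist[prep.record_idx].T.copy()
    return out
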