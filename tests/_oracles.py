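"""Independent reference implementations used only to cross-check the package.

Everything here is written naively and directly from the model definitions
(explicit Euler at a tiny step, closed forms, hand-built linear systems),
deliberately sharing no code with the package's integrator.
"""

from __future__ import annotations

import numpy as np


def cascade_appearance(t, m0, k1, k2):
    """Closed-form appearance rate of a linear two-compartment cascade.

    A mass ``m0`` empties from compartment 1 at rate ``k1`` into compartment
    2, which releases at rate ``k2``: appearance(t) = k1 k2 m0
    (e^(-k1 t) - e^(-k2 t)) / (k2 - k1).
    """
    t = np.asarray(t, dtype=float)
    if abs(k1 - k2) < 1e-12:
        return k1 * k2 * m0 * t * np.exp(-k1 * t)
    return k1 * k2 * m0 * (np.exp(-k1 * t) - np.exp(-k2 * t)) / (k2 - k1)


def euler_glucose(log, params, absorption, step=0.01, record_every=5.0, G0=None, I0=None):
    """Explicit-Euler simulation of the full combined model at a tiny step.

    Follows the model equations literally with per-nutrient scalar state,
    per-administration depot pairs and a dense glucose history for the
    delayed term (linear interpolation on the fine grid).  Slow but simple;
    the independent oracle for the package's RK4 integrator.
    """
    n = int(round(log.duration / step))
    # digestion state
    sto = {"mono": 0.0, "lipid": 0.0, "protein": 0.0, "fiber": 0.0}
    sto_starch: list[list] = []  # [mass, gi]
    int_starch: list[list] = []
    int_mono = 0.0
    # depots: [S1, S2, t_max_i]
    depots: list[list] = []
    G = float(G0)
    I = float(I0)
    hist = np.empty(n + 1)
    hist[0] = G
    meals = {round(m.time / step): m for m in log.meals}
    doses = {}
    for ins in log.insulins:
        doses.setdefault(round(ins.time / step), []).append(ins)

    out_t, out_g, out_i = [], [], []
    rec = round(record_every / step)
    for i in range(n + 1):
        if i in meals:
            c = meals[i].composition
            sto["mono"] += c.monosaccharide_g
            sto["lipid"] += c.lipid_g
            sto["protein"] += c.protein_g
            sto["fiber"] += c.fiber_g
            for mass, gi in c.starch_portions:
                sto_starch.append([mass, gi])
                int_starch.append([0.0, gi])
        if i in doses:
            for ins in doses[i]:
                depots.append([ins.dose_iu * 6000.0 / log.body_weight_kg, 0.0, ins.t_max_i])
        if i % rec == 0:
            out_t.append(i * step)
            out_g.append(G)
            out_i.append(I)
        if i == n:
            break
        # digestion derivatives
        k_e = absorption.k_ge / (
            1.0
            + absorption.c_lipid * sto["lipid"]
            + absorption.c_protein * sto["protein"]
            + absorption.c_fiber * sto["fiber"]
        )
        appearance = absorption.k_abs * int_mono
        d_int_mono = k_e * sto["mono"] - appearance
        new_sto = {k: v - step * k_e * v for k, v in sto.items()}
        for j, (mass, gi) in enumerate(sto_starch):
            flux = k_e * mass
            hyd = absorption.k_hyd_ref * gi * int_starch[j][0]
            sto_starch[j][0] = mass - step * flux
            int_starch[j][0] += step * (flux - hyd)
            d_int_mono += hyd
        sto = new_sto
        int_mono += step * d_int_mono
        # delayed glucose, linear interpolation on the fine grid
        s = i * step - params.tau_G
        if s <= 0:
            g_del = hist[0]
        else:
            j0 = int(s / step)
            th = s / step - j0
            g_del = (1 - th) * hist[j0] + th * hist[min(j0 + 1, i)]
        x = max(g_del, 0.0) / params.G_star
        f_del = x**params.gamma / (1.0 + x**params.gamma)
        release = sum(d[1] / d[2] for d in depots)
        delta_a = appearance / 180.16 * 1000.0 / (params.V_G * log.body_weight_kg)
        dG = -params.K_xgi * G * I + params.T_GH / params.V_G + delta_a
        dI = -params.K_xi * I + (params.T_iGmax / params.V_I) * f_del + release / params.V_I
        for d in depots:
            s1, s2, tmax = d
            d[0] = s1 - step * s1 / tmax
            d[1] = s2 + step * (s1 - s2) / tmax
        G += step * dG
        I += step * dI
        hist[i + 1] = G
    return np.array(out_t), np.array(out_g), np.array(out_i)


def periodic_cubic_spline(x_knots, y_knots, period, xq):
    """Hand-built equally-spaced periodic natural cubic spline evaluation.

    Solves the classical cyclic tridiagonal system for the knot second
    derivatives (M_{i-1} + 4 M_i + M_{i+1} = 6 (y_{i-1} - 2 y_i + y_{i+1}) / h^2)
    and evaluates the piecewise cubic directly.
    """
    x_knots = np.asarray(x_knots, dtype=float)
    y = np.asarray(y_knots, dtype=float)
    k = len(y)
    h = period / k
    assert np.allclose(np.diff(x_knots), h), "knots must be equally spaced"
    A = np.zeros((k, k))
    rhs = np.zeros(k)
    for i in range(k):
        A[i, (i - 1) % k] = 1.0
        A[i, i] = 4.0
        A[i, (i + 1) % k] = 1.0
        rhs[i] = 6.0 * (y[(i - 1) % k] - 2.0 * y[i] + y[(i + 1) % k]) / h**2
    M = np.linalg.solve(A, rhs)

    xq = np.mod(np.asarray(xq, dtype=float) - x_knots[0], period) + x_knots[0]
    out = np.empty(xq.shape)
    for idx, xv in np.ndenumerate(xq):
        i = min(int((xv - x_knots[0]) / h), k - 1)
        x0 = x_knots[0] + i * h
        y0, y1 = y[i], y[(i + 1) % k]
        m0, m1 = M[i], M[(i + 1) % k]
        a = (x0 + h - xv) / h
        b = (xv - x0) / h
        out[idx] = (
            a * y0
            + b * y1
            + ((a**3 - a) * m0 + (b**3 - b) * m1) * h**2 / 6.0
        )
    return out
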