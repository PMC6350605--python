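# Methods

`glucopred` predicts the blood-glucose level (BGL) of an insulin-treated
diabetic outpatient a few hours ahead, from nothing but a lifestyle log:
timestamped meals with nutrient composition, subcutaneous insulin doses,
continuous glucose monitor (CGMS) readings and occasional fingerstick
self-measurements. This note documents the models, the numerical scheme,
the personalization machinery, the virtual-patient generator used in place
of clinical data, and the design decisions and limitations a user should
know about.

## The combined model

### Meal digestion

Digestion is a two-compartment mass balance (stomach, intestine) over five
nutrient classes. Every stomach species empties into the intestine at a
common first-order rate that is slowed by the lipid, protein and fiber
mass currently in the stomach:

    k_empty = k_ge / (1 + c_lipid·L + c_protein·P + c_fiber·F)

Starch is tracked in per-glycemic-index (GI) pools and hydrolyses to
monosaccharide in the intestine at rate `k_hyd_ref · GI`; intestinal
monosaccharide crosses the gut wall at rate `k_abs`, giving the plasma
appearance rate (g/min). Lipid, protein and fiber empty but contribute no
glucose. Overlapping meals superpose; pools with equal GI merge. The
appearance rate is converted into a concentration rate
`ΔaMonosac = appearance / 180.16 · 1000 / (V_G · kgBW)` (mmol/l/min).

Defaults (1/min unless noted): `k_ge` 0.028, `k_hyd_ref` 0.023, `k_abs`
0.023, `c_lipid` = `c_protein` 0.02 /g, `c_fiber` 0.05 /g. They give
physiologically plausible appearance peaks 30–90 min after a meal
(slower for low-GI and high-fat meals). Digestion is assumed identical
across subjects — diabetes is not a digestion disorder — so these
constants are population-level and never trained.

### Glucose–insulin control

The control model is a delay-differential system with per-administration
subcutaneous depots (units: min, mmol/l, pM):

    dG/dt  = −K_xgi·G·I + T_GH/V_G + ΔaMonosac(t)
    dI/dt  = −K_xi·I + (T_iGmax/V_I)·f(G(t−τ_G)) + Σ S2/(V_I·t_max,I)
    dS1/dt = −S1/t_max,I            (one depot pair per injection)
    dS2/dt = (S1 − S2)/t_max,I
    f(G)   = (G/G*)^γ / (1 + (G/G*)^γ)

`f` is the endogenous (pancreatic) release fraction: 0 at zero glycaemia,
1/2 at `G*`, saturating at 1, with `γ` controlling steepness. An injection
of `d` IU adds `d·6000/kgBW` pmol/kgBW to a fresh S1 depot (1 IU = 6 nmol);
each administration keeps its own depot pair because the time-to-maximum
absorption `t_max,I` is product-dependent (registry defaults: rapid analog
55 min, regular 90 min, NPH 300 min, long-acting analog 600 min). Basal
insulin is modelled exactly like a bolus with a long `t_max,I`.

Default parameters are population-level optimized literature values:
`K_xgi` 3.11e−5 1/(min·pM), `T_GH` 0.003 mmol/(min·kgBW), `V_G` 0.187
l/kgBW, `K_xi` 1.211e−2 1/min, `T_iGmax` 0.1 pmol/(min·kgBW), `V_I` 0.236
l/kgBW, `τ_G` 24 min, `G*` 9 mmol/l, `γ` 3.205.

Initial conditions: `G0` is the log's first glucose measurement (the basal
steady state if the log has none); `I0` is the steady-state insulin of the
candidate parameter set, obtained by bracketed bisection on the scalar
equilibrium condition (the uptake term is strictly increasing in G, so the
root is unique); depots and stomach start empty.

## Numerical scheme

The system is triangular: digestion and the depots do not depend on
(G, I). The integrator exploits this as a two-pass cascade on one fixed
1-min clock:

1. **Shared pass** (once per log window): digestion and depots advance
   with classical RK4 at half the step, recording the appearance rate and
   the depot release sum `Σ S2/t_max,I` at every half-step node — exactly
   the RK4 stage times of the second pass. Meals and injections are
   discrete state updates at their (grid-aligned) timestamps.
2. **Batched pass**: (G, I) advance with RK4 for a whole matrix of
   candidate parameter vectors at once, reading the recorded inputs.

The delayed glucose `G(t−τ_G)` is interpolated from the integrator's own
history by a cubic Hermite scheme using the stored step-endpoint
derivatives. Linear interpolation would cap the method at second order;
with Hermite interpolation step-halving changes 5-min samples by less
than 1e−6 mmol/l on smooth segments, and the trajectory agrees with a
0.01-min explicit-Euler reference to better than 1e−3 mmol/l over a 6-h
meal-plus-bolus scenario. Carbohydrate mass balance (stomach + intestine +
cumulative absorbed = ingested) and insulin mass balance (injected = depot
residual + cumulative plasma appearance) hold to rounding because the
cumulative terms are co-integrated states of the same RK4 pass.

`f` is evaluated with its argument clipped at zero (a transiently negative
delayed G would otherwise raise a non-integer power of a negative number);
no other clamping is applied. A candidate whose trajectory loses
finiteness is reported as infeasible (fitness +∞) rather than crashing
the search. Model restarts (below) and events land on step boundaries, so
every RK4 step integrates a smooth segment.

**Model restart.** At a fingerstick measurement the predicted G is set to
the measured value while I and all depots are kept — digestion and insulin
kinetics that overlap the measurement are still modelled. The glucose
history is re-seeded to the measured value over one delay span, so the
delayed pancreatic term also sees the corrected level. This is how a
lifestyle application would deploy routine pre-meal self-measurements to
cancel accumulated drift.

## Personalization

Fitness of a candidate is the RMSE (mmol/l) between the log's CGMS
readings and a continuous simulation of the window with restarts at every
fingerstick. Candidates are dimensionless multipliers of the reference
parameters, bounded to [0.2, 5.0] ("clinically plausible"); trainable
subsets are 3 (`K_xgi`, `K_xi`, `V_I`), 6 (+ `T_GH`, `V_G`, `T_iGmax`) or
9 (all). Search strategies:

- **OFAT sensitivity**: one-parameter sweeps around the reference.
- **Brute force**: exhaustive additive grid, 7 steps of 20% per parameter
  (multipliers 0.4…1.6), i.e. exactly 343 evaluations for 3 parameters.
  A geometric grid is available but additive is the default.
- **Genetic algorithm**: real-coded; tournament selection (size 3), blend
  crossover (α = 0.5, probability 0.9), per-gene Gaussian mutation
  (σ = 0.1), elitism of one, reference vector seeded into the initial
  population. Presets: *fast* (pop 10 × gen 10, mutation 1%) and *slow*
  (pop 50 × gen 50, mutation 20%). Fully deterministic under a seed.
- **Nelder–Mead refinement**: downhill simplex from a previous result,
  initial simplex spanned by +5% perturbations, 100 iterations, candidates
  clipped to bounds; returns the start if no improvement is found, so the
  pipeline fitness is monotone non-increasing.

A generation (or grid chunk) is evaluated as one vectorized batch against
the prepared window, which is what makes the 2 550-evaluation slow GA
affordable (seconds per generation on a 3-day log).

### Structural identifiability — a known limitation

Glucose-only fitness is *exactly* invariant under the rescaling
`(K_xgi, V_I) → (c·K_xgi, c·V_I)`: every insulin source and sink is linear
in I, so the rescaling multiplies the whole insulin trajectory by 1/c
while the uptake term `K_xgi·G·I` — the only place insulin touches
glucose — is unchanged. CGMS data therefore determine `K_xi` and the ratio
`K_xgi/V_I`, never `K_xgi` and `V_I` separately; the fitness landscape has
an exactly flat valley along the gauge direction, and an unconstrained
search (GA, simplex) returns an arbitrary point on it. Grid search is
immune in practice only because the default grid contains a single pair
with the right ratio. Predictions are unaffected — all points on the orbit
produce identical glucose trajectories — but recovered per-parameter
values must not be interpreted physiologically. The same caveat applies
(with more gauge freedom) to the 6- and 9-parameter sets.

### Diurnal profiles

Insulin sensitivity varies over the day; a time-constant model accumulates
its worst errors at night. The day is split into four 6-h periods
(0–6, 6–12, 12–18, 18–24 h); the profiled parameter (default `K_xi`) is
re-trained once per period against only that period's CGMS samples, while
the simulation always runs continuously over the whole window (digestion
and depots cross period boundaries). The four multipliers become knots of
a periodic cubic spline anchored at the period midpoints (3:00, 9:00,
15:00, 21:00), so the curve is C¹ everywhere including midnight and passes
through each trained value at its period centre. Spline overshoot beyond
the multiplier bounds is clipped, not re-fit. A period without CGMS
samples keeps the global trained value (multiplier 1) with a warning.
A constant profile of 1.0 reproduces the non-diurnal simulation
bit-identically.

## Evaluation

- **Error metrics**: mean |error|, max |error|, variance of the signed
  error, RMSE — all on prediction−CGMS pairs at CGMS timestamps.
- **Clarke Error Grid Analysis**: pairs are converted to mg/dl (×18.016)
  and zoned A–E by the original grid geometry; boundary points go to the
  less severe zone. A+B is the clinically acceptable fraction. The D zone
  captures the clinically worst case — an overly high prediction when the
  patient is actually hypoglycaemic.
- **Meal-wise protocol**: the model starts fresh at each meal (anchored at
  the nearest CGMS sample within ±10 min, empty stomach and depots,
  steady-state insulin, no knowledge of earlier events) and runs 1–6 h.
  Errors pooled across meals per horizon quantify how ignoring overlapping
  digestion/insulin history degrades longer predictions.
- **Full-log protocol**: continuous simulation of the whole record with
  all events, restarts on or off.
- **Sliding-window cross-validation**: a 1- or 2-day training window
  slides from t = 0 in 3-h steps; at each position the pipeline trains on
  the window and the 1-h meal-wise RMSE is measured on the meals outside
  it; fold RMSEs are averaged. Inside a 3-day log a 2-day window admits at
  most 9 positions at the 3-h step (10 would need a 75-h record); paired
  comparisons here use 8 positions for both widths.
- **Welch two-sample t-test** (α = 0.05) supports improvement claims.

Caveat on the 1-day-vs-2-day comparison: the two configurations evaluate
*different* meal sets (whatever lies outside each window), so the
comparison confounds training width with evaluation-set composition. On
virtual patients the confound is of the same order as the training effect
and can run in either direction; the package reports both numbers and
leaves the interpretation to the user.

## Virtual patients

Clinical logs of this kind are not publicly shareable, so testing and
calibration use virtual patients with known ground truth:

- **Parameters**: planted multipliers (for recovery tests) or log-normal
  draws (median 1.0, log-sd 0.2, truncated to the identification bounds).
  Optionally a planted diurnal `K_xi` profile.
- **Schedule** (per day): three main meals near 7:30, 12:30 and 18:30
  (Gaussian time jitter, sd 20 min) drawn from a small built-in food table
  with log-normal size jitter (sd 0.15); a rapid-analog bolus at each meal
  dosed at 0.6 IU per 10 g carbohydrate with ±20% jitter (dosing by
  experience, deliberately imperfect) rounded to half units; 10 IU of
  long-acting basal at 22:00; a fingerstick 10 min before each meal. The
  dosing defaults were chosen so simulated glucose is realistic for
  insulin-treated outpatients (median ≈ 7–10 mmol/l, under 3% of time
  below 3.9 mmol/l).
- **CGMS noise**: multiplicative, `value = truth·(1+ε)` at 5-min cadence,
  with ε the sum of a white component and an AR(1) drift (time constant
  120 min) holding 40% of the variance; drift amplitude grows 10% per
  sensor-day (sensors degrade over their six-day lifetime). The total sd
  is calibrated analytically (σ = mean_rel·√(π/2)) so the mean absolute
  relative error is ≈17% — at typical diabetic glucose levels this also
  puts the median absolute difference near 1.4 mmol/l, matching clinical
  CGMS evaluations in outpatient use. Fingersticks carry independent 5% CV
  noise (a plausible placeholder; meter specifications vary).

What the generator does *not* emulate: physical activity and stress (out
of the model's scope), sensor dropouts and calibration events, food-log
mistakes, and carbohydrate appearing from protein/lipid metabolism. A
passing recovery test therefore shows the pipeline is correct and
self-consistent, not that real patients' parameters are recoverable at
these tolerances.

## Problem sizes and defaults used in the shipped checks

The test suite and the acceptance script run on 1- and 3-day virtual
patients (288/864 CGMS samples), 1-min integration steps, the 3-parameter
space for recovery checks and the 6-parameter space + Nelder–Mead +
diurnal for the headline trained pipeline; cross-validation uses the fast
GA preset and 8 window positions. These sizes make a full run complete in
minutes on one core while exercising every stage at realistic data
volumes (a real 3-week log is only ~7× longer).

## Known limitations

- The control model ignores renal glucose clearance, exercise, stress and
  incretin effects; `T_GH` lumps hepatic output and insulin-independent
  uptake into one constant.
- The absorption equations are a committed first-order structure with
  fixed population constants, not a fitted digestion model.
- Parameter estimates are predictive, not physiological (see structural
  identifiability above).
- CGMS error is treated as noise to average over; no device-error
  correction or adaptive retraining is attempted.
- Basal insulin as a long-`t_max,I` bolus underrepresents the flat plateau
  of modern basal analogs.
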