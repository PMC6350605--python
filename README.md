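# glucopred

Personalized blood-glucose prediction for insulin-treated diabetic
outpatients, from nothing but a lifestyle log: timestamped meals with
nutrient composition, subcutaneous insulin doses, continuous glucose
monitor (CGMS) readings and fingerstick self-measurements.

Diabetics choose their insulin doses by experience and conjecture; a model
that predicts the blood-glucose level (BGL) a few hours ahead from the
data a phone app can collect would let them check a decision before acting
on it. `glucopred` implements such a predictor and everything needed to
train and evaluate it — including a virtual-patient simulator that stands
in for clinical logs, which are not publicly shareable.

## The model

A two-compartment digestion model (stomach → intestine, five nutrient
classes, glycemic-index-dependent starch hydrolysis, gastric emptying
retarded by lipids/proteins/fibers) produces the meal-derived glucose
appearance rate ΔaMonosac(t). It drives a delay-differential
glucose–insulin control system with per-injection subcutaneous depots
(units: min, mmol/l, pM):

    dG/dt  = −K_xgi·G·I + T_GH/V_G + ΔaMonosac(t)
    dI/dt  = −K_xi·I + (T_iGmax/V_I)·f(G(t−τ_G)) + Σ S2/(V_I·t_max,I)
    dS1/dt = −S1/t_max,I ,   dS2/dt = (S1 − S2)/t_max,I
    f(G)   = (G/G*)^γ / (1 + (G/G*)^γ)

where `f` is the endogenous insulin release fraction (half-maximal at
`G* = 9 mmol/l`) and each injection feeds its own S1→S2 depot pair with a
product-dependent time-to-maximum absorption `t_max,I`. The system is
integrated with fixed-step RK4 (1 min), the delay handled by cubic Hermite
interpolation of the glucose history.

Personalization multiplies a subset of the nine control parameters
(3: `K_xgi, K_xi, V_I`; 6: + `T_GH, V_G, T_iGmax`; 9: all) by trained
multipliers in [0.2, 5], minimizing the RMSE between simulation and CGMS
with model restarts at every fingerstick. Searches: exhaustive grid
(7 × 20% steps), a real-coded genetic algorithm (fast and slow presets),
and Nelder–Mead refinement — optionally per 6-hour day period, smoothed
into a periodic spline diurnal profile of insulin sensitivity. Predictions
are scored by RMSE and by Clarke Error Grid Analysis (zone A+B =
clinically acceptable). See `docs/methods.md` for the full account,
including a structural identifiability caveat: glucose data determine
`K_xi` and the ratio `K_xgi/V_I`, never `K_xgi` and `V_I` separately.

## Worked example

Generate a 3-day virtual patient, personalize the three main parameters,
and evaluate the prediction against its CGMS record:

```sh
$ glucopred simulate --days 3 --seed 11 --out log.csv --truth-out truth.csv
wrote log.csv: 9 meals, 12 injections, 864 CGMS samples, 9 fingersticks

$ glucopred train log.csv --method ga-fast --params 3 --refine-nm --seed 2 --out params.json
trained ga_fast+nelder_mead: RMSE 1.872 mmol/l (267 evaluations) -> params.json

$ glucopred evaluate log.csv --params-file params.json --out eval.json
{
 "average_error": 1.3380433665947526,
 "max_error": 9.797796833061266,
 "variance": 3.4944250486879334,
 "rmse": 1.8715141767217185
}
```

The trained model tracks this patient's noisy CGMS record with a 1.87
mmol/l RMSE and a 1.34 mmol/l mean absolute error over the full three
days (the CGMS itself carries a ~17% relative error, so much of this is
the sensor, not the model). `eval.json` also contains the error-grid zone
fractions; `params.json` holds the trained multipliers and absolute
parameter values and can be fed back into `glucopred predict` for new
windows of the same patient.

Other subcommands: `predict` (trajectory CSV), `crossval` (sliding-window
1-h prediction error), `sensitivity` (one-factor-at-a-time parameter
sweep), and `run` (YAML-configured simulate → train → evaluate pipeline
with a single fan-out seed). The log file format is documented below.

## Log file format

CSV (or an equivalent JSON mirror) with `# key=value` header lines
(`patient_id`, `duration`, `day_phase` — minutes of clock time at t = 0)
and one row per event:

| column(s) | row type | meaning |
|---|---|---|
| `time` | all | minutes since log start |
| `type` | all | `meal`, `insulin`, `cgms`, `fingerstick`, `weight` |
| `mono_g, starch_g, gi, lipid_g, protein_g, fiber_g` | meal | grams; `gi` in (0, 1.5]; several rows at one time = portions of one meal |
| `dose_iu, product` | insulin | product resolves `t_max,I` via the registry (`rapid_analog`, `regular`, `nph`, `long_analog`, extensible) |
| `value_mmol_l` or `value_mg_dl` | cgms / fingerstick | mg/dl divided by 18.016 on read |
| `weight_kg` | weight | body weight (required once) |

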