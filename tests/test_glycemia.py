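import numpy as np
import pytest
from scipy.optimize import fsolve

from glucopred import engine
from glucopred.absorption import AbsorptionParams
from glucopred.glycemia import (
    DepotPair,
    GlycemiaParams,
    ModelState,
    derivatives,
    endogenous_release_fraction,
    inject_insulin,
    restart,
    simulate,
    steady_state,
)
from glucopred.lifestyle_log import (
    GlucoseMeasurement,
    InsulinEvent,
    MealEvent,
    NutrientComposition,
    PatientLog,
)

from _oracles import euler_glucose

TINY = 1e-30  # stands in for "term switched off" while params stay positive


def _empty_log(duration=1440.0, weight=80.0):
    return PatientLog(patient_id="t", body_weight_kg=weight, duration=duration)


def _meal_bolus_log(duration=360.0):
    """6-h scenario: one mixed meal plus one rapid bolus at t = 30 min."""
    comp = NutrientComposition(20.0, [(40.0, 1.0)], 10.0, 20.0, 5.0)
    return PatientLog(
        patient_id="t",
        body_weight_kg=80.0,
        meals=[MealEvent(30.0, comp)],
        insulins=[InsulinEvent(30.0, 6.0, "rapid_analog", "bolus", 55.0)],
        duration=duration,
    )


class TestReleaseFraction:
    def test_half_maximal_at_g_star(self):
        assert endogenous_release_fraction(9.0, 9.0, 3.205) == 0.5

    def test_zero_glycaemia(self):
        assert endogenous_release_fraction(0.0) == 0.0

    def test_high_precision_point(self):
        expected = 2.0**3.205 / (1.0 + 2.0**3.205)  # 0.90205...
        assert endogenous_release_fraction(18.0, 9.0, 3.205) == pytest.approx(
            expected, rel=1e-14
        )
        assert expected == pytest.approx(0.9021, abs=1e-4)

    def test_monotone_and_saturating(self):
        g = np.linspace(0.0, 60.0, 500)
        f = endogenous_release_fraction(g, 9.0, 3.205)
        assert np.all(np.diff(f) > 0)
        assert endogenous_release_fraction(1e6) == pytest.approx(1.0, abs=1e-9)
        assert np.all((f >= 0) & (f < 1))


class TestInjectInsulin:
    def test_dose_conversion(self):
        state = ModelState(t=0.0, G=9.0, I=40.0)
        out = inject_insulin(
            state, InsulinEvent(0.0, 10.0, "rapid_analog", "bolus", 55.0), 80.0
        )
        assert out.depots[-1].S1 == pytest.approx(750.0)  # 10 * 6000 / 80
        assert out.depots[-1].S2 == 0.0

    def test_total_depot_mass_increases_by_dose(self):
        state = ModelState(t=0.0, G=9.0, I=40.0, depots=[DepotPair(100.0, 50.0, 90.0)])
        out = inject_insulin(
            state, InsulinEvent(0.0, 4.0, "regular", "bolus", 90.0), 60.0
        )
        before = sum(d.S1 + d.S2 for d in state.depots)
        after = sum(d.S1 + d.S2 for d in out.depots)
        assert after - before == pytest.approx(4.0 * 6000.0 / 60.0)

    def test_two_products_get_independent_depots(self):
        state = ModelState(t=0.0, G=9.0, I=40.0)
        state = inject_insulin(
            state, InsulinEvent(0.0, 5.0, "rapid_analog", "bolus", 55.0), 80.0
        )
        state = inject_insulin(
            state, InsulinEvent(0.0, 10.0, "long_analog", "basal", 600.0), 80.0
        )
        assert [d.t_max_i for d in state.depots] == [55.0, 600.0]


class TestDerivatives:
    def test_decoupled_decay(self):
        params = GlycemiaParams(K_xgi=TINY, T_GH=TINY, T_iGmax=TINY)
        state = ModelState(t=0.0, G=7.0, I=50.0, G_history=[(0.0, 7.0)])
        d = derivatives(state, params)
        assert d.dG == pytest.approx(0.0, abs=1e-12)
        assert d.dI == pytest.approx(-params.K_xi * 50.0, rel=1e-9)

    def test_steady_state_matches_independent_root_finder(self, ref_params):
        G_ss, I_ss = steady_state(ref_params)

        def system(x):
            g, i = x
            f = (g / ref_params.G_star) ** ref_params.gamma
            f /= 1.0 + f
            return [
                -ref_params.K_xgi * g * i + ref_params.T_GH / ref_params.V_G,
                -ref_params.K_xi * i + ref_params.T_iGmax / ref_params.V_I * f,
            ]

        oracle = fsolve(system, x0=[9.0, 20.0], full_output=False)
        assert G_ss == pytest.approx(oracle[0], rel=1e-8)
        assert I_ss == pytest.approx(oracle[1], rel=1e-8)
        state = ModelState(t=0.0, G=G_ss, I=I_ss, G_history=[(0.0, G_ss)])
        d = derivatives(state, ref_params)
        assert d.dG == pytest.approx(0.0, abs=1e-12)
        assert d.dI == pytest.approx(0.0, abs=1e-12)

    def test_depot_chain_delivers_full_dose_to_plasma(self):
        # with insulin elimination and secretion switched off, the plasma
        # gain is the injected depot content divided by V_I
        params = GlycemiaParams(K_xi=TINY, T_iGmax=TINY, body_weight_kg=80.0)
        log = _empty_log(duration=4000.0)
        log.insulins = [InsulinEvent(0.0, 6.0, "rapid_analog", "bolus", 55.0)]
        traj = simulate(
            log, params, restart_at_fingersticks=False, G0=9.0, I0=0.0
        )
        s1_0 = 6.0 * 6000.0 / 80.0
        assert traj.I_pM.iloc[-1] == pytest.approx(s1_0 / params.V_I, rel=1e-4)


class TestIntegrator:
    def test_steady_state_run_is_flat_for_24h(self, ref_params):
        G_ss, I_ss = steady_state(ref_params)
        traj = simulate(_empty_log(1440.0), ref_params, G0=G_ss, I0=I_ss)
        assert np.max(np.abs(traj.G_mmol_l - G_ss)) < 1e-6

    def test_step_halving_is_below_1e6(self, ref_params):
        log = _meal_bolus_log()
        a = simulate(log, ref_params, G0=9.0, step=1.0)
        b = simulate(log, ref_params, G0=9.0, step=0.5)
        assert np.max(np.abs(a.G_mmol_l.values - b.G_mmol_l.values)) < 1e-6

    def test_agrees_with_small_step_euler_oracle(self, ref_params):
        log = _meal_bolus_log()
        _, I_ss = steady_state(ref_params)
        rk4 = simulate(log, ref_params, G0=9.0, step=1.0)
        t, g, _ = euler_glucose(
            log, ref_params, AbsorptionParams(), step=0.01, G0=9.0, I0=I_ss
        )
        assert np.array_equal(t, rk4.t_min.values)
        assert np.max(np.abs(g - rk4.G_mmol_l.values)) < 1e-3

    def test_insulin_mass_balance(self):
        log = _meal_bolus_log(duration=720.0)
        prep = engine.prepare_window(log, AbsorptionParams(), G0=9.0)
        recovered = prep.insulin_depot_residual_pmol_kg + prep.insulin_absorbed_pmol_kg
        assert recovered == pytest.approx(prep.insulin_injected_pmol_kg, rel=1e-10)

    def test_nonnegativity_across_parameter_bounds(self, short_log_noisefree):
        log, _ = short_log_noisefree
        rng = np.random.default_rng(42)
        space_names = ("K_xgi", "K_xi", "V_I", "T_GH", "V_G", "T_iGmax")
        mult = rng.uniform(0.2, 5.0, size=(16, len(space_names)))
        prep = engine.prepare_window(log, None)
        batch = engine.params_to_batch(GlycemiaParams(body_weight_kg=80.0), space_names, mult)
        out = engine.run_batch(prep, batch, return_insulin=True)
        assert out["ok"].all()
        assert np.all(out["G"] >= 0.0)
        assert np.all(out["I"] >= 0.0)

    def test_blow_up_names_the_parameters(self):
        # a absurdly large uptake rate makes the trajectory non-finite
        log = _meal_bolus_log()
        params = GlycemiaParams(K_xgi=3.11e-5 * 1e9)
        with pytest.raises(FloatingPointError, match="K_xgi"):
            simulate(log, params, G0=9.0)


class TestRestart:
    def test_contract_resets_glucose_only(self):
        state = ModelState(
            t=100.0, G=9.0, I=50.0,
            depots=[DepotPair(200.0, 80.0, 55.0)],
            G_history=[(60.0, 8.0), (100.0, 9.0)],
        )
        out = restart(state, GlucoseMeasurement(100.0, 6.5, "fingerstick"))
        assert out.G == 6.5
        assert out.I == 50.0
        assert out.depots[0].S1 == 200.0 and out.depots[0].S2 == 80.0
        assert {g for _, g in out.G_history} == {6.5}

    def test_fixed_point_when_measurement_equals_state(self):
        state = ModelState(t=50.0, G=7.5, I=40.0, G_history=[(0.0, 7.0), (50.0, 7.5)])
        out = restart(state, GlucoseMeasurement(50.0, 7.5, "fingerstick"))
        assert out.G == state.G and out.I == state.I

    def test_restarts_reduce_error_from_a_wrong_initial_condition(
        self, planted_patient_noisefree
    ):
        spec, log, truth = planted_patient_noisefree
        params = spec.true_params()
        cgms = log.cgms_values()
        wrong_g0 = cgms[0] + 2.0  # deliberate +2 mmol/l initial error
        with_restart = simulate(
            log, params, G0=wrong_g0, record_times=log.cgms_times(),
            restart_at_fingersticks=True,
        )
        without = simulate(
            log, params, G0=wrong_g0, record_times=log.cgms_times(),
            restart_at_fingersticks=False,
        )
        rmse_on = np.sqrt(np.mean((with_restart.G_mmol_l.values - cgms) ** 2))
        rmse_off = np.sqrt(np.mean((without.G_mmol_l.values - cgms) ** 2))
        assert rmse_on < rmse_off

    def test_rejects_cgms_source_and_bad_values(self):
        state = ModelState(t=10.0, G=9.0, I=50.0)
        with pytest.raises(ValueError):
            restart(state, GlucoseMeasurement(10.0, 6.5, "cgms"))
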