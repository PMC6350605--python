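import numpy as np
import pytest

from glucopred.glycemia import GlycemiaParams, steady_state
from glucopred.identification import (
    PRESET_PARAMS,
    FitnessEvaluator,
    ParameterSpace,
    TrainingConfig,
    brute_force,
    fitness,
    ga_optimize,
    nelder_mead_refine,
    ofat_sensitivity,
    train,
)
from glucopred.lifestyle_log import GlucoseMeasurement, PatientLog


class QuadraticSurrogate:
    """Stand-in fitness ||m - target||^2 with the evaluator interface."""

    def __init__(self, target):
        self.target = np.asarray(target, dtype=float)
        self.n_evaluations = 0

    def __call__(self, multipliers):
        m = np.atleast_2d(np.asarray(multipliers, dtype=float))
        self.n_evaluations += m.shape[0]
        return np.sum((m - self.target) ** 2, axis=1)

    def scalar(self, multipliers):
        return float(self(np.atleast_2d(multipliers))[0])


def _flat_log(offset=0.0, duration=1440.0):
    """Log whose CGMS is the model's own steady state plus an offset.

    A fingerstick at t=0 pins the simulation to the true steady state, so
    the prediction is constant and the CGMS offset maps directly to RMSE.
    """
    params = GlycemiaParams(body_weight_kg=80.0)
    G_ss, _ = steady_state(params)
    measurements = [GlucoseMeasurement(0.0, G_ss, "fingerstick")] + [
        GlucoseMeasurement(t, G_ss + offset, "cgms")
        for t in np.arange(5.0, duration, 5.0)
    ]
    return params, PatientLog(
        patient_id="flat", body_weight_kg=80.0,
        measurements=measurements, duration=duration,
    )


class TestFitness:
    def test_zero_when_model_matches_cgms(self):
        params, log = _flat_log(offset=0.0)
        assert fitness(log, params) == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_gives_offset_rmse(self):
        params, log = _flat_log(offset=2.0)
        assert fitness(log, params) == pytest.approx(2.0, abs=1e-9)

    def test_blow_up_becomes_inf_sentinel_not_crash(self, short_log_noisefree):
        log, _ = short_log_noisefree
        space = ParameterSpace(("K_xgi",), GlycemiaParams(body_weight_kg=80.0),
                               lower=0.5, upper=1e12)
        ev = FitnessEvaluator(log, space)
        assert ev.scalar(np.array([1e9])) == np.inf


class TestOFAT:
    def test_structure_baseline_and_sensitivity(self, short_log_noisefree):
        log, _ = short_log_noisefree
        space = ParameterSpace.preset(3, GlycemiaParams(body_weight_kg=80.0))
        mult = [0.6, 1.0, 1.6]
        table = ofat_sensitivity(log, mult, space)
        assert len(table) == len(space.names) * len(mult)
        baseline = table[table.multiplier == 1.0].fitness
        assert baseline.nunique() == 1  # identical no-change row everywhere
        span = np.ptp(table[table.parameter == "K_xgi"].fitness.values)
        assert span > 0.0

    def test_requires_baseline_multiplier(self, short_log_noisefree):
        log, _ = short_log_noisefree
        space = ParameterSpace.preset(3, GlycemiaParams(body_weight_kg=80.0))
        with pytest.raises(ValueError, match="1.0"):
            ofat_sensitivity(log, [0.5, 1.5], space)


class TestBruteForce:
    def test_evaluation_count_law_and_grid(self):
        space = ParameterSpace(PRESET_PARAMS[3])
        ev = QuadraticSurrogate([0.8, 1.2, 1.0])
        config = TrainingConfig(method="brute_force", bf_steps=7, bf_step_size=0.2)
        result = brute_force(None, space, config, evaluator=ev)
        assert ev.n_evaluations == 7**3 == result.n_evaluations == 343
        # the planted optimum sits exactly on the additive 20% grid
        assert result.vector(space.names) == pytest.approx([0.8, 1.2, 1.0])

    def test_degenerate_single_step_grid(self):
        space = ParameterSpace(("K_xgi", "K_xi"))
        ev = QuadraticSurrogate([0.7, 0.7])
        config = TrainingConfig(method="brute_force", bf_steps=1)
        result = brute_force(None, space, config, evaluator=ev)
        assert result.n_evaluations == 1
        assert result.vector(space.names) == pytest.approx([1.0, 1.0])

    def test_even_step_count_rejected(self):
        space = ParameterSpace(("K_xgi",))
        with pytest.raises(ValueError, match="odd"):
            brute_force(None, space, TrainingConfig(bf_steps=6), evaluator=QuadraticSurrogate([1.0]))


class TestGeneticAlgorithm:
    def test_seeded_determinism(self):
        space = ParameterSpace(PRESET_PARAMS[3])
        config = TrainingConfig.ga_fast(seed=7)
        r1 = ga_optimize(None, space, config, evaluator=QuadraticSurrogate([0.9, 1.1, 1.0]))
        r2 = ga_optimize(None, space, config, evaluator=QuadraticSurrogate([0.9, 1.1, 1.0]))
        assert r1.multipliers == r2.multipliers
        assert r1.fitness == r2.fitness

    def test_different_seeds_may_differ(self):
        space = ParameterSpace(PRESET_PARAMS[3])
        results = {
            ga_optimize(
                None, space, TrainingConfig.ga_fast(seed=s),
                evaluator=QuadraticSurrogate([0.9, 1.1, 1.0]),
            ).fitness
            for s in range(4)
        }
        assert len(results) > 1

    def test_elitism_beats_reference_start(self, short_log_noisefree):
        log, _ = short_log_noisefree
        space = ParameterSpace.preset(3, GlycemiaParams(body_weight_kg=80.0))
        ev = FitnessEvaluator(log, space)
        ref_fitness = ev.scalar(np.ones(3))
        result = ga_optimize(log, space, TrainingConfig.ga_fast(seed=0), evaluator=ev)
        assert result.fitness <= ref_fitness

    def test_converges_on_surrogate_within_bounds(self):
        space = ParameterSpace(PRESET_PARAMS[3])
        config = TrainingConfig.ga_slow(seed=3)
        result = ga_optimize(None, space, config, evaluator=QuadraticSurrogate([0.7, 1.4, 1.0]))
        vec = result.vector(space.names)
        assert np.all((vec >= space.lower) & (vec <= space.upper))
        assert result.fitness < 0.01  # close to the planted optimum


class TestNelderMead:
    def test_converges_on_quadratic_surrogate(self):
        space = ParameterSpace(PRESET_PARAMS[3])
        result = nelder_mead_refine(
            None, space, np.ones(3), evaluator=QuadraticSurrogate([1.1, 1.1, 1.1])
        )
        assert result.vector(space.names) == pytest.approx([1.1, 1.1, 1.1], abs=1e-4)

    def test_stationary_at_an_optimum(self):
        space = ParameterSpace(("K_xgi", "K_xi"))
        ev = QuadraticSurrogate([1.0, 1.0])
        result = nelder_mead_refine(None, space, np.ones(2), evaluator=ev)
        assert result.vector(space.names) == pytest.approx([1.0, 1.0], abs=1e-6)

    def test_monotone_improvement_contract(self, short_log_noisefree):
        log, _ = short_log_noisefree
        space = ParameterSpace.preset(3, GlycemiaParams(body_weight_kg=80.0))
        ev = FitnessEvaluator(log, space)
        ga = ga_optimize(log, space, TrainingConfig.ga_fast(seed=1), evaluator=ev)
        refined = nelder_mead_refine(log, space, ga, max_iter=40, evaluator=ev)
        assert refined.fitness <= ga.fitness
        vec = refined.vector(space.names)
        assert np.all((vec >= space.lower) & (vec <= space.upper))


def test_train_pipeline_dispatch(short_log_noisefree):
    log, _ = short_log_noisefree
    space = ParameterSpace.preset(3, GlycemiaParams(body_weight_kg=80.0))
    result = train(log, space, TrainingConfig.ga_fast(seed=5), refine=False)
    assert result.method == "ga_fast"
    assert result.fitness >= 0.0
    with pytest.raises(ValueError, match="unknown training method"):
        train(log, space, TrainingConfig(method="gradient"), refine=False)
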