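import numpy as np
import pytest
from scipy import stats

from glucopred.evaluation import (
    PredictionResult,
    cross_validate,
    ega_classify,
    ega_report,
    error_metrics,
    full_run,
    improvement_ttest,
    meal_wise_test,
)
from glucopred.glycemia import GlycemiaParams
from glucopred.identification import ParameterSpace, TrainingConfig
from glucopred.lifestyle_log import GlucoseMeasurement, PatientLog


def _result(predicted, reference):
    predicted = np.asarray(predicted, dtype=float)
    return PredictionResult(
        times=np.arange(len(predicted), dtype=float),
        predicted=predicted,
        reference=np.asarray(reference, dtype=float),
    )


class TestErrorMetrics:
    def test_identical_series_all_zero(self):
        m = error_metrics(_result([5.0, 6.0, 7.0], [5.0, 6.0, 7.0]))
        assert m == {"average_error": 0.0, "max_error": 0.0, "variance": 0.0, "rmse": 0.0}

    def test_constant_offset(self):
        m = error_metrics(_result([7.0, 8.0], [5.0, 6.0]))
        assert m["average_error"] == m["max_error"] == m["rmse"] == 2.0
        assert m["variance"] == 0.0

    def test_hand_computed_mixed_errors(self):
        m = error_metrics(_result([5.0, 4.0, 9.0], [4.0, 6.0, 6.0]))  # errors 1,-2,3
        assert m["average_error"] == pytest.approx(2.0)
        assert m["max_error"] == pytest.approx(3.0)
        assert m["rmse"] == pytest.approx(np.sqrt(14.0 / 3.0))
        assert m["rmse"] == pytest.approx(2.160, abs=1e-3)

    def test_two_point_hand_rmse(self):
        m = error_metrics(_result([5.0, 7.0], [4.0, 9.0]))
        assert m["rmse"] == pytest.approx(np.sqrt(5.0 / 2.0))
        assert m["rmse"] == pytest.approx(1.5811, abs=1e-4)

    def test_empty_result_raises(self):
        with pytest.raises(ValueError):
            error_metrics(_result([], []))

    def test_rmse_dominates_average_error(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            e = rng.normal(0, 2, size=rng.integers(2, 200))
            m = error_metrics(_result(e + 6.0, np.full(e.size, 6.0)))
            assert m["rmse"] >= m["average_error"] - 1e-12


class TestEGA:
    def test_perfect_prediction_is_zone_a(self):
        assert ega_classify(6.3, 6.3) == "A"

    def test_dangerous_overestimate_in_hypo_range_is_d(self):
        # reference 3 mmol/l (54 mg/dl) predicted 7 mmol/l (126 mg/dl)
        assert ega_classify(7.0, 3.0) == "D"

    def test_benign_underestimate_at_high_glucose_is_b(self):
        # the same 4 mmol/l error is acceptable at 12 mmol/l reference
        assert ega_classify(8.0, 12.0) == "B"

    def test_both_hypo_is_a_regardless_of_ratio(self):
        assert ega_classify(2.0, 3.5) == "A"  # both below 70 mg/dl

    def test_gross_mismatches_are_e(self):
        assert ega_classify(11.0, 3.5) == "E"  # 198 vs 63 mg/dl
        assert ega_classify(3.5, 11.0) == "E"

    def test_every_pair_gets_exactly_one_zone_and_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        pred = rng.uniform(1.0, 25.0, 4000)
        ref = rng.uniform(1.0, 25.0, 4000)
        report = ega_report(_result(pred, ref))
        assert set(np.unique(report.zones)) <= set("ABCDE")
        assert sum(report.fractions.values()) == pytest.approx(1.0)
        assert report.acceptable == report.fractions["A"] + report.fractions["B"]

    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            ega_classify(0.0, 5.0)


class TestFullRun:
    def test_no_fingersticks_makes_restart_a_noop(self, short_log_noisefree):
        log, _ = short_log_noisefree
        stripped = PatientLog(
            patient_id=log.patient_id,
            body_weight_kg=log.body_weight_kg,
            meals=log.meals,
            insulins=log.insulins,
            measurements=log.cgms(),
            duration=log.duration,
        )
        params = GlycemiaParams(body_weight_kg=80.0)
        on = full_run(stripped, params, restart=True)
        off = full_run(stripped, params, restart=False)
        assert np.array_equal(on.predicted, off.predicted)

    def test_restart_keeps_the_prediction_points(self, short_log_noisefree):
        log, _ = short_log_noisefree
        params = GlycemiaParams(body_weight_kg=80.0)
        on = full_run(log, params, restart=True)
        off = full_run(log, params, restart=False)
        assert len(on.predicted) == len(off.predicted) == len(log.cgms())
        assert np.array_equal(on.times, off.times)


class TestMealWise:
    def test_single_meal_pooling_is_that_meal(self, short_log_noisefree):
        log, _ = short_log_noisefree
        params = GlycemiaParams(body_weight_kg=80.0)
        one_meal = PatientLog(
            patient_id="p", body_weight_kg=80.0, meals=log.meals[:1],
            insulins=[i for i in log.insulins if i.time <= log.meals[0].time + 120],
            measurements=log.measurements, duration=log.duration,
        )
        out = meal_wise_test(one_meal, params, horizons=(120.0,))
        assert out[120.0]["n_meals"] == 1
        # 120-min horizon at 5-min cadence: 24 scored samples after the anchor
        assert len(out[120.0]["result"].predicted) == 24

    def test_meal_without_anchor_is_skipped(self, short_log_noisefree):
        log, _ = short_log_noisefree
        params = GlycemiaParams(body_weight_kg=80.0)
        sparse = PatientLog(
            patient_id="p", body_weight_kg=80.0, meals=log.meals,
            insulins=log.insulins,
            # CGMS only in the first two hours: later meals have no anchor
            measurements=[m for m in log.cgms() if m.time <= 120.0],
            duration=log.duration,
        )
        with pytest.warns(UserWarning, match="no CGMS anchor"):
            with pytest.raises(ValueError, match="no meal admitted"):
                meal_wise_test(sparse, params, horizons=(60.0,))

    def test_metrics_present_per_horizon(self, reference_patient_noisy):
        _, log, _ = reference_patient_noisy
        params = GlycemiaParams(body_weight_kg=80.0)
        out = meal_wise_test(log, params, horizons=(60.0, 240.0))
        for h in (60.0, 240.0):
            assert {"average_error", "max_error", "variance", "rmse"} <= set(out[h]["metrics"])
            assert out[h]["n_meals"] == 9


class TestCrossValidate:
    def test_positions_one_is_a_single_split(self, planted_patient_noisy):
        _, log, _ = planted_patient_noisy
        config = TrainingConfig(method="brute_force", bf_steps=1, seed=0)
        space = ParameterSpace.preset(3, GlycemiaParams(body_weight_kg=80.0))
        out = cross_validate(log, 1, positions=1, space=space, config=config)
        assert out["mean_rmse"] == out["fold_rmse"][0]
        assert len(out["fold_rmse"]) == 1

    def test_mean_is_arithmetic_mean_of_folds(self, planted_patient_noisy):
        _, log, _ = planted_patient_noisy
        config = TrainingConfig(method="brute_force", bf_steps=1, seed=0)
        space = ParameterSpace.preset(3, GlycemiaParams(body_weight_kg=80.0))
        out = cross_validate(log, 1, positions=3, space=space, config=config)
        assert out["mean_rmse"] == pytest.approx(np.mean(out["fold_rmse"]))

    def test_too_short_log_reports_feasible_positions(self, short_log_noisefree):
        log, _ = short_log_noisefree  # 1 day long
        with pytest.raises(ValueError, match="at most"):
            cross_validate(log, 1, positions=10)


class TestImprovementTTest:
    def test_identical_samples(self):
        out = improvement_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)
        assert not out["significant"]

    def test_swapping_groups_negates_t(self):
        a, b = [1.0, 2.0, 5.0, 3.0], [4.0, 6.0, 5.0]
        ab = improvement_ttest(a, b)
        ba = improvement_ttest(b, a)
        assert ab["t"] == pytest.approx(-ba["t"])
        assert ab["p"] == pytest.approx(ba["p"])

    def test_welch_hand_example(self):
        out = improvement_ttest([1, 2, 3, 4, 5], [3, 4, 5, 6, 7])
        assert out["t"] == pytest.approx(-2.0)
        assert out["p"] == pytest.approx(0.0805, abs=5e-4)
        assert not out["significant"]
        # agrees with the scipy reference implementation
        t_ref, p_ref = stats.ttest_ind([1, 2, 3, 4, 5], [3, 4, 5, 6, 7], equal_var=False)
        assert out["t"] == pytest.approx(t_ref)

    def test_zero_variance_identical_means(self):
        out = improvement_ttest([2.0, 2.0], [2.0, 2.0])
        assert out == {"t": 0.0, "p": 1.0, "significant": False}

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            improvement_ttest([1.0], [1.0, 2.0])
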