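import numpy as np
import pytest

from teendrive.calibration import (
    CalibrationProblem,
    OptimizerSettings,
    bootstrap_ci,
    calibrate,
    objective,
)
from teendrive.model import SimulationConfig, Trajectory

from conftest import SHARED_TRUTH, truth_candidate


class TestObjective:
    def test_zero_at_truth_on_noiseless_panel(self, small_noiseless):
        panel, truth, problem = small_noiseless
        assert objective(truth_candidate(truth), problem) < 1e-25

    def test_increases_with_perturbation(self, small_noiseless):
        panel, truth, problem = small_noiseless
        f_prev = 0.0
        for delta in (1.0, 5.0, 25.0):
            bumped = [
                Trajectory(t.driver_id, t.months, t.events + (delta if t.driver_id == panel[0].driver_id else 0), t.miles)
                for t in panel
            ]
            prob = CalibrationProblem(panel=tuple(bumped), config=problem.config)
            f = objective(truth_candidate(truth), prob)
            assert f > f_prev
            f_prev = f

    def test_hand_computed_standardised_mse(self):
        # one driver, two months, all feedbacks off: simulated events/miles
        # are constant (rate*need, need); pooled MSE standardised by the
        # observed series' population variances, averaged over 2*D*M terms
        obs = Trajectory("d1", [1, 2], [8.0, 12.0], [90.0, 110.0])
        problem = CalibrationProblem(
            panel=(obs,),
            shared_params=("beta1", "beta2", "beta3", "event_decay_time"),
            individual_params=("driving_need", "initial_event_rate"),
        )
        cand = {
            "beta1": 0.0, "beta2": 0.0, "beta3": 0.0, "event_decay_time": 5.0,
            "driving_need": 100.0, "initial_event_rate": 0.1,
        }
        # simulated: events = 10, 10; miles = 100, 100
        var_e, var_m = np.var([8.0, 12.0]), np.var([90.0, 110.0])
        expected = ((4 + 4) / var_e + (100 + 100) / var_m) / 4
        assert objective(cand, problem) == pytest.approx(expected, rel=1e-12)

    def test_penalty_is_finite_on_blowup(self, small_noiseless):
        _, truth, problem = small_noiseless
        cand = truth_candidate(truth)
        cand["beta2"] = -0.05  # extreme feedback still simulates; force decay blowup
        cand["event_decay_time"] = 0.1
        f = objective(cand, problem)
        assert np.isfinite(f)


class TestCalibrate:
    def test_recovers_truth_on_noiseless_panel(self, small_noiseless):
        _, truth, problem = small_noiseless
        res = calibrate(problem, OptimizerSettings(n_starts=40, seed=2))
        assert res.objective < 1e-8
        for name, val in SHARED_TRUTH.items():
            assert res.estimates[name] == pytest.approx(val, rel=5e-3)
        need = res.estimates["driving_need"]
        for row in truth.itertuples():
            assert need[row.driver_id] == pytest.approx(row.driving_need, rel=1e-2)

    def test_permutation_invariance(self, small_noiseless, fast_settings):
        panel, _, problem = small_noiseless
        res1 = calibrate(problem, fast_settings)
        shuffled = CalibrationProblem(panel=tuple(reversed(panel)), config=problem.config)
        res2 = calibrate(shuffled, fast_settings)
        for name in SHARED_TRUTH:
            assert res1.estimates[name] == pytest.approx(res2.estimates[name], rel=1e-9)

    def test_more_starts_never_worse(self, small_noiseless):
        _, _, problem = small_noiseless
        f1 = calibrate(problem, OptimizerSettings(n_starts=1, seed=7, explore_iter=1, n_polish=1)).objective
        f2 = calibrate(problem, OptimizerSettings(n_starts=12, seed=7, explore_iter=1, n_polish=12)).objective
        assert f2 <= f1 + 1e-12

    def test_deterministic_given_seed(self, small_noiseless, fast_settings):
        _, _, problem = small_noiseless
        r1 = calibrate(problem, fast_settings)
        r2 = calibrate(problem, fast_settings)
        assert r1.objective == r2.objective
        assert r1.estimates["beta1"] == r2.estimates["beta1"]

    def test_underdetermined_warning(self):
        months = np.arange(1, 3)
        panel = (Trajectory("d0", months, [5.0, 6.0], [100.0, 110.0]),)
        problem = CalibrationProblem(panel=panel)
        res = calibrate(problem, OptimizerSettings(n_starts=4, seed=1, explore_iter=1, n_polish=1, max_iter=5))
        assert any("underdetermined" in w for w in res.warnings)

    def test_aggregate_mode_fits_single_pseudo_driver(self, small_noiseless, fast_settings):
        _, _, problem = small_noiseless
        agg = CalibrationProblem(panel=problem.panel, config=problem.config, aggregate=True)
        res = calibrate(agg, fast_settings)
        assert len(res.per_driver_fit) == 1
        assert res.per_driver_fit[0].driver_id == "aggregate"


class TestPartitionValidation:
    def test_overlap_rejected(self):
        t = Trajectory("d", [1, 2], [1.0, 2.0], [10.0, 20.0])
        with pytest.raises(ValueError):
            CalibrationProblem(panel=(t,), shared_params=("beta1", "driving_need"),
                               individual_params=("driving_need", "initial_event_rate"))

    def test_missing_coverage_rejected(self):
        t = Trajectory("d", [1, 2], [1.0, 2.0], [10.0, 20.0])
        with pytest.raises(ValueError, match="missing"):
            CalibrationProblem(panel=(t,), shared_params=("beta1", "beta2"),
                               individual_params=("driving_need",))

    def test_unknown_name_rejected(self):
        t = Trajectory("d", [1, 2], [1.0, 2.0], [10.0, 20.0])
        with pytest.raises(ValueError, match="unknown"):
            CalibrationProblem(panel=(t,), shared_params=("beta1", "beta2", "beta3", "event_decay_time", "gamma"),
                               individual_params=("driving_need", "initial_event_rate"))


class TestBootstrap:
    def test_noiseless_intervals_tight_around_truth(self, small_noiseless):
        _, _, problem = small_noiseless
        settings = OptimizerSettings(n_starts=6, seed=3, explore_iter=1, n_polish=1, max_iter=30)
        ci = bootstrap_ci(problem, settings, n_boot=4, seed=12)
        for name, val in SHARED_TRUTH.items():
            lo, hi = ci[name]
            assert lo <= hi
            # resampled noiseless drivers still identify the shared truth
            assert lo == pytest.approx(val, rel=0.25)
            assert hi == pytest.approx(val, rel=0.25)

    def test_requires_two_replicates(self, small_noiseless):
        _, _, problem = small_noiseless
        with pytest.raises(ValueError):
            bootstrap_ci(problem, OptimizerSettings(n_starts=2), n_boot=1, seed=0)
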