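import numpy as np
import pytest

from teendrive.model import (
    DriverState,
    ModelParameters,
    SimulationConfig,
    Trajectory,
    events_per_mile,
    monthly_driving,
    simulate_driver,
    step,
)


def params(**kw) -> ModelParameters:
    base = dict(
        beta1=-0.00025,
        beta2=-0.008,
        beta3=-3.40216,
        event_decay_time=6.15949,
        risky_fraction=0.07,
        driving_need=548.85,
        initial_event_rate=0.05,
    )
    base.update(kw)
    return ModelParameters(**base)


class TestEventsPerMile:
    @pytest.mark.parametrize(
        "state,overrides,expected",
        [
            (DriverState(0, 0), dict(initial_event_rate=0.03), 0.03),
            (DriverState(0, 1000), dict(beta1=-0.00025), 0.05 * np.exp(-0.25)),
            (DriverState(100, 0), dict(beta2=-0.008), 0.05 * np.exp(-0.8)),
        ],
    )
    def test_exponential_law(self, state, overrides, expected):
        assert events_per_mile(state, params(**overrides)) == pytest.approx(expected, rel=1e-12)

    def test_strictly_positive(self):
        assert events_per_mile(DriverState(1e4, 1e6), params()) > 0


class TestMonthlyDriving:
    @pytest.mark.parametrize(
        "recent,need,expected",
        [
            (0.0, 548.85, 548.85),
            (10.0, 600.0, 600.0 - 3.40216 * 10),
            (100.0, 300.0, 0.0),  # raw value −40.216 clamps to zero miles
        ],
    )
    def test_linear_law_with_clamp(self, recent, need, expected):
        got = monthly_driving(DriverState(recent_events=recent), params(driving_need=need))
        assert got == pytest.approx(expected, rel=1e-12)


class TestStep:
    def test_pure_decay(self):
        p = params(risky_fraction=0.0, event_decay_time=5.0)
        s = step(DriverState(recent_events=10.0), p, dt=1.0)
        assert s.recent_events == pytest.approx(8.0)

    def test_miles_accumulate(self):
        p = params(driving_need=500.0, beta3=0.0)
        s = step(DriverState(cumulative_miles=1000.0), p, dt=1.0)
        assert s.cumulative_miles == pytest.approx(1500.0)

    def test_full_flow_balance(self):
        # rate 0.04, driving 500 at the incoming state, frac 0.07, tau 6.15949
        p = params(
            beta1=0.0, beta2=0.0, beta3=0.0,
            initial_event_rate=0.04, driving_need=500.0,
            risky_fraction=0.07, event_decay_time=6.15949,
        )
        s = step(DriverState(recent_events=10.0), p, dt=1.0)
        expected = 10.0 + (0.04 * 500 * 0.07 - 10.0 / 6.15949)
        assert s.recent_events == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(9.776, abs=5e-4)

    def test_recent_events_clamped_nonnegative(self):
        p = params(risky_fraction=0.0, event_decay_time=0.5)
        s = step(DriverState(recent_events=10.0), p, dt=1.0)
        assert s.recent_events == 0.0


class TestSimulateDriver:
    def test_monotone_decline_without_recent_feedback(self):
        p = params(risky_fraction=0.0)
        traj = simulate_driver(p, SimulationConfig(horizon=8))
        epm = traj.events_per_mile
        assert np.all(np.diff(epm) < 0)

    def test_no_feedback_is_constant(self):
        p = params(beta1=0.0, beta2=0.0, beta3=0.0, driving_need=600.0)
        traj = simulate_driver(p, SimulationConfig(horizon=6))
        assert np.allclose(traj.miles, 600.0)
        assert np.allclose(traj.events_per_mile, p.initial_event_rate)

    def test_cumulative_miles_nondecreasing_and_stocks_nonnegative(self):
        p = params(driving_need=400.0)
        cfg = SimulationConfig(horizon=12, initial_recent_events=150.0)
        traj = simulate_driver(p, cfg)
        assert np.all(traj.miles >= 0)
        assert np.all(traj.events >= 0)

    def test_simulation_matches_repeated_steps(self):
        p = params()
        cfg = SimulationConfig(horizon=4, initial_recent_events=50.0)
        traj = simulate_driver(p, cfg)
        state = DriverState(recent_events=50.0)
        for m in range(4):
            ev = events_per_mile(state, p) * monthly_driving(state, p)
            mi = monthly_driving(state, p)
            assert traj.events[m] == pytest.approx(ev, rel=1e-12)
            assert traj.miles[m] == pytest.approx(mi, rel=1e-12)
            state = step(state, p, 1.0)

    def test_euler_decay_approaches_closed_form(self):
        # with no inflow the recent-events stock is linear decay; at dt=1/64
        # the Euler solution must match R0*exp(-t/tau) within 1%
        tau, r0, horizon = 6.15949, 100.0, 5
        p = params(risky_fraction=0.0, event_decay_time=tau, beta3=0.0)
        cfg = SimulationConfig(dt=1 / 64, horizon=horizon, initial_recent_events=r0)
        from teendrive.model import simulate_cohort_paths

        _, _, recent, _ = simulate_cohort_paths(
            p.beta1, p.beta2, p.beta3, tau, 0.0, p.driving_need,
            p.initial_event_rate, np.array([r0]), 0.0,
            months=horizon, steps_per_month=64,
        )
        exact = r0 * np.exp(-np.arange(horizon + 1) / tau)
        assert np.max(np.abs(recent[:, 0] - exact) / exact) < 0.01

    def test_two_half_steps_converge_quadratically(self):
        # explicit Euler: richardson-style check that halving dt shrinks the
        # local step discrepancy by ~4x
        p = params(driving_need=600.0, risky_fraction=0.07)
        s0 = DriverState(recent_events=80.0, cumulative_miles=100.0)

        def discrepancy(dt):
            full = step(s0, p, dt)
            half = step(step(s0, p, dt / 2), p, dt / 2)
            return abs(full.recent_events - half.recent_events)

        d1, d2 = discrepancy(1.0), discrepancy(0.5)
        assert d2 < d1 / 3.0  # O(dt^2) contraction, allowing slack


class TestValidation:
    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            params(event_decay_time=0.0)
        with pytest.raises(ValueError):
            params(initial_event_rate=0.0)
        with pytest.raises(ValueError):
            params(risky_fraction=1.5)
        with pytest.raises(ValueError):
            params(driving_need=-1.0)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.3)  # does not divide one month evenly
        with pytest.raises(ValueError):
            SimulationConfig(horizon=0)

    def test_trajectory_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            Trajectory("d1", [1, 2], [1.0], [100.0, 200.0])

    def test_events_per_mile_nan_where_no_driving(self):
        t = Trajectory("d1", [1, 2], [0.0, 5.0], [0.0, 100.0])
        epm = t.events_per_mile
        assert np.isnan(epm[0]) and epm[1] == pytest.approx(0.05)
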