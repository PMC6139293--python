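import numpy as np
import pytest

from teendrive.calibration import CalibrationProblem, OptimizerSettings
from teendrive.model import ModelParameters, SimulationConfig, simulate_driver
from teendrive.synthetic import (
    CohortSpec,
    LognormalSpec,
    NoiseSpec,
    default_shared_parameters,
    generate_cohort,
)

#: published point estimates of the shared parameters
SHARED_TRUTH = {
    "beta1": -0.00025,
    "beta2": -0.00800,
    "beta3": -3.40216,
    "event_decay_time": 6.15949,
}

#: printed 95% confidence intervals for the shared parameters
SHARED_CI = {
    "beta1": (-0.00027, -0.00023),
    "beta2": (-0.00827, -0.00758),
    "beta3": (-3.59304, -3.27073),
    "event_decay_time": (5.68868, 6.69635),
}


@pytest.fixture(scope="session")
def shared_params() -> ModelParameters:
    return default_shared_parameters()


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A small, fast cohort for calibration plumbing tests."""
    return CohortSpec(n_drivers=6, seed=11)


def noiseless_panel(spec: CohortSpec):
    """Exact (unrounded) deterministic panel plus the generating truth."""
    coh = generate_cohort(
        CohortSpec(
            n_drivers=spec.n_drivers,
            months=spec.months,
            shared=spec.shared,
            need_distribution=spec.need_distribution,
            rate_distribution=spec.rate_distribution,
            initial_recent_events=spec.initial_recent_events,
            noise=NoiseSpec(poisson_events=False, miles_sd=0.0),
            seed=spec.seed,
        )
    )
    config = SimulationConfig(
        horizon=spec.months, initial_recent_events=spec.initial_recent_events
    )
    panel = [
        simulate_driver(
            coh.shared.replace(
                driving_need=row.driving_need,
                initial_event_rate=row.initial_event_rate,
            ),
            config,
            driver_id=row.driver_id,
        )
        for row in coh.truth.itertuples()
    ]
    return panel, coh.truth, config


def truth_candidate(truth_df):
    cand = dict(SHARED_TRUTH)
    cand["driving_need"] = truth_df.set_index("driver_id")["driving_need"].to_dict()
    cand["initial_event_rate"] = truth_df.set_index("driver_id")[
        "initial_event_rate"
    ].to_dict()
    return cand


@pytest.fixture(scope="session")
def small_noiseless(small_spec):
    panel, truth, config = noiseless_panel(small_spec)
    problem = CalibrationProblem(panel=tuple(panel), config=config)
    return panel, truth, problem


@pytest.fixture
def fast_settings() -> OptimizerSettings:
    return OptimizerSettings(n_starts=12, seed=5, explore_iter=1, n_polish=1, max_iter=25)
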