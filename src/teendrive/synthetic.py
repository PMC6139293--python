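"""Synthetic driver-month cohorts for calibration and diagnostics testing.

Generates panels with the statistical structure of a 47-driver, 5-month
novice-driver cohort: each driver follows the deterministic two-stock model
with individually drawn ``driving_need`` and ``initial_event_rate``
(lognormal heterogeneity, positive by construction), observed through a
Poisson count model for monthly events and multiplicative lognormal noise on
monthly miles.  Each event is independently flagged as a collision with
probability ``risky_fraction`` (collisions are the risky-perceived events,
about 7% of all events).

The generating truth is always returned alongside the observed panel: the
module exists to support parameter-recovery experiments, so the truth is a
first-class output, never hidden state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParameters, Trajectory, simulate_cohort_paths

__all__ = [
    "LognormalSpec",
    "NoiseSpec",
    "CohortSpec",
    "SyntheticCohort",
    "default_shared_parameters",
    "generate_cohort",
    "summarize_cohort",
]

#: Shared (fixed-effect) parameter defaults: the published point estimates of
#: the two-stock model, plus the 7% collision (risky-perceived) share.
DEFAULT_SHARED = dict(
    beta1=-0.00025,
    beta2=-0.00800,
    beta3=-3.40216,
    event_decay_time=6.15949,
    risky_fraction=0.07,
)


def default_shared_parameters(
    driving_need: float = 925.0, initial_event_rate: float = 0.130
) -> ModelParameters:
    """Shared defaults as a full parameter set (per-driver fields at their
    cohort means)."""
    return ModelParameters(
        driving_need=driving_need,
        initial_event_rate=initial_event_rate,
        **DEFAULT_SHARED,
    )


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal distribution parametrised by its mean and sd (natural units).

    ``sd = 0`` degenerates to a point mass at ``mean``.
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValueError("lognormal mean must be > 0")
        if self.sd < 0:
            raise ValueError("lognormal sd must be >= 0")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(size, self.mean)
        cv2 = (self.sd / self.mean) ** 2
        sigma = math.sqrt(math.log1p(cv2))
        mu = math.log(self.mean) - sigma**2 / 2
        return rng.lognormal(mu, sigma, size)


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise switches.

    ``poisson_events``: monthly events drawn Poisson with mean equal to the
    latent rate times observed miles (off: rounded latent counts).
    ``miles_sd``: sigma of mean-one multiplicative lognormal noise on miles
    (0 disables).
    """

    poisson_events: bool = True
    miles_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.miles_sd < 0:
            raise ValueError("miles_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Study-design description of a synthetic cohort.

    Defaults reproduce the reference cohort: 47 drivers followed 5 months,
    shared parameters at the published estimates, driver heterogeneity and
    the initial recent-events stock set so the cohort-mean event rate sits
    near 0.05 events/mile and peaks in month 2 while monthly miles stay in
    the 500-700 band.
    """

    n_drivers: int = 47
    months: int = 5
    shared: ModelParameters = field(default_factory=default_shared_parameters)
    need_distribution: LognormalSpec = LognormalSpec(mean=925.0, sd=275.0)
    rate_distribution: LognormalSpec = LognormalSpec(mean=0.130, sd=0.123)
    initial_recent_events: float = 126.0
    noise: NoiseSpec = NoiseSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drivers < 1:
            raise ValueError("n_drivers must be >= 1")
        if self.months < 2:
            raise ValueError("months must be >= 2")
        if self.initial_recent_events < 0:
            raise ValueError("initial_recent_events must be >= 0")


@dataclass
class SyntheticCohort:
    """Observed panel plus the generating truth."""

    panel: list[Trajectory]
    truth: pd.DataFrame  # per-driver generating parameters
    shared: ModelParameters
    spec: CohortSpec


def generate_cohort(spec: CohortSpec = CohortSpec()) -> SyntheticCohort:
    """Draw one synthetic cohort; byte-reproducible given ``spec.seed``.

    Per driver: individual parameters are drawn from the spec distributions,
    the latent trajectory is simulated deterministically, then observed.
    Observed monthly events are Poisson with mean (latent rate x observed
    miles); collisions are a binomial thinning of observed events at
    ``risky_fraction``.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.n_drivers
    need = spec.need_distribution.draw(rng, d)
    rate = spec.rate_distribution.draw(rng, d)
    s = spec.shared
    events, miles, _, _ = simulate_cohort_paths(
        s.beta1, s.beta2, s.beta3, s.event_decay_time, s.risky_fraction,
        need, rate, spec.initial_recent_events, 0.0, months=spec.months,
    )
    if not (np.all(np.isfinite(events)) and np.all(np.isfinite(miles))):
        bad = np.where(~np.isfinite(events + miles).all(axis=0))[0]
        raise ValueError(f"non-finite latent trajectory for driver draw(s) {bad.tolist()}")

    if spec.noise.miles_sd > 0:
        sig = spec.noise.miles_sd
        miles_obs = miles * np.exp(rng.normal(0.0, sig, miles.shape) - sig**2 / 2)
    else:
        miles_obs = miles.copy()
    # events are counts around the latent trajectory (rate x latent miles):
    # reporting noise on miles does not alter the driver's actual exposure
    if spec.noise.poisson_events:
        events_obs = rng.poisson(events).astype(float)
    else:
        events_obs = np.round(events)
    collisions = rng.binomial(events_obs.astype(np.int64), s.risky_fraction).astype(float)

    width = len(str(d))
    ids = [f"d{i + 1:0{width}d}" for i in range(d)]
    months_idx = np.arange(1, spec.months + 1)
    panel = [
        Trajectory(
            driver_id=ids[i],
            months=months_idx,
            events=events_obs[:, i],
            miles=miles_obs[:, i],
            collisions=collisions[:, i],
        )
        for i in range(d)
    ]
    truth = pd.DataFrame(
        {
            "driver_id": ids,
            "driving_need": need,
            "initial_event_rate": rate,
            "initial_recent_events": np.full(d, spec.initial_recent_events),
        }
    )
    return SyntheticCohort(panel=panel, truth=truth, shared=s, spec=spec)


def summarize_cohort(panel: list[Trajectory]) -> pd.DataFrame:
    """Per-month cross-driver mean and sd of events, miles and events/mile.

    The event-rate column averages per-driver monthly ratios; months where a
    driver logged zero miles are excluded from that driver's rate (not set
    to zero).  Shape mirrors the standard cohort summary table: one row per
    follow-up month.
    """
    if not panel:
        raise ValueError("empty panel")
    months = panel[0].months
    ev = np.stack([t.events for t in panel], axis=1)
    mi = np.stack([t.miles for t in panel], axis=1)
    epm = np.stack([t.events_per_mile for t in panel], axis=1)
    with np.errstate(invalid="ignore"):
        out = pd.DataFrame(
            {
                "month": months,
                "events_mean": ev.mean(axis=1),
                "events_sd": ev.std(axis=1, ddof=1) if ev.shape[1] > 1 else 0.0,
                "miles_mean": mi.mean(axis=1),
                "miles_sd": mi.std(axis=1, ddof=1) if mi.shape[1] > 1 else 0.0,
                "epm_mean": np.nanmean(epm, axis=1),
                "epm_sd": np.nanstd(epm, axis=1, ddof=1) if epm.shape[1] > 1 else 0.0,
            }
        ).set_index("month")
    return out
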