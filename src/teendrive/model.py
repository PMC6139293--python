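"""Two-stock system-dynamics model of novice-driver risky driving.

The model tracks two stocks for each driver — ``recent_events`` (risky-driving
events still salient to the driver) and ``cumulative_miles`` (total exposure
since licensure) — and three flows: monthly driving adds to cumulative miles,
new events add to recent events, and old events drain recent events with a
mean residence time ``event_decay_time``.

Two behavioural laws close the system:

* events per mile  = ``initial_event_rate * exp(beta1*C + beta2*R)`` — both
  accumulated experience (C) and salient recent events (R) reduce the event
  rate (``beta1, beta2 < 0``);
* monthly driving  = ``driving_need + beta3*R`` — recent events suppress
  driving (``beta3 < 0``), clamped at zero miles.

Integration is explicit (forward) Euler with flows evaluated at the
start-of-step state, the natural discretisation when observations are monthly
and the feedback delays are several months long.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "DriverState",
    "SimulationConfig",
    "Trajectory",
    "events_per_mile",
    "monthly_driving",
    "step",
    "simulate_driver",
    "simulate_cohort_paths",
]


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the driver model.

    Attributes
    ----------
    beta1:
        Effect of cumulative miles driven on log events-per-mile
        (per mile; expected negative).
    beta2:
        Effect of the recent-events stock on log events-per-mile
        (per event; expected negative).
    beta3:
        Effect of the recent-events stock on monthly driving
        (miles/month per event; expected negative).
    event_decay_time:
        Mean time for an event to leave the recent-events stock (months).
    risky_fraction:
        Fraction of events perceived as risky by the driver, in [0, 1].
    driving_need:
        Monthly driving when the recent-events stock is zero (miles/month).
    initial_event_rate:
        Events per mile when both stocks are zero (events/mile); this is
        exp(beta0) of the log-linear event-rate law.
    """

    beta1: float
    beta2: float
    beta3: float
    event_decay_time: float
    risky_fraction: float
    driving_need: float
    initial_event_rate: float

    def __post_init__(self) -> None:
        if not self.event_decay_time > 0:
            raise ValueError("event_decay_time must be > 0")
        if not self.initial_event_rate > 0:
            raise ValueError("initial_event_rate must be > 0")
        if not 0.0 <= self.risky_fraction <= 1.0:
            raise ValueError("risky_fraction must lie in [0, 1]")
        if self.driving_need < 0:
            raise ValueError("driving_need must be >= 0")

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DriverState:
    """State of one driver: the two stocks and the clock."""

    recent_events: float = 0.0
    cumulative_miles: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.recent_events < 0 or self.cumulative_miles < 0 or self.time < 0:
            raise ValueError("stocks and time must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Time grid and initial stocks for a simulation run.

    ``dt`` must divide one month evenly so that sub-steps aggregate cleanly
    into calendar months; ``horizon`` is a whole number of months.
    """

    dt: float = 1.0
    horizon: int = 5
    initial_recent_events: float = 0.0
    initial_cumulative_miles: float = 0.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if int(self.horizon) != self.horizon or self.horizon <= 0:
            raise ValueError("horizon must be a positive whole number of months")
        spm = 1.0 / self.dt
        if abs(spm - round(spm)) > 1e-9:
            raise ValueError("dt must divide one month evenly (1/dt integer)")
        if self.initial_recent_events < 0 or self.initial_cumulative_miles < 0:
            raise ValueError("initial stocks must be non-negative")

    @property
    def steps_per_month(self) -> int:
        return int(round(1.0 / self.dt))


@dataclass
class Trajectory:
    """Per-month series (events, miles) for one driver, simulated or observed.

    ``events`` holds events per month (all events, not only the risky-perceived
    subset), ``miles`` miles per month.  ``collisions`` is optional and only
    populated by the synthetic-cohort generator.  The event rate is derived,
    with NaN marking months of zero driving.
    """

    driver_id: str
    months: np.ndarray
    events: np.ndarray
    miles: np.ndarray
    collisions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.months = np.asarray(self.months, dtype=int)
        self.events = np.asarray(self.events, dtype=float)
        self.miles = np.asarray(self.miles, dtype=float)
        if not (len(self.months) == len(self.events) == len(self.miles)):
            raise ValueError("months, events and miles must have equal length")
        if np.any(self.events < 0) or np.any(self.miles < 0):
            raise ValueError("events and miles must be non-negative")
        if self.collisions is not None:
            self.collisions = np.asarray(self.collisions, dtype=float)
            if len(self.collisions) != len(self.months):
                raise ValueError("collisions length mismatch")

    @property
    def events_per_mile(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = self.events / self.miles
        return np.where(self.miles > 0, rate, np.nan)

    def __len__(self) -> int:
        return len(self.months)


def events_per_mile(state: DriverState, params: ModelParameters) -> float:
    """Event rate at a state: ``initial_event_rate * exp(beta1*C + beta2*R)``."""
    return params.initial_event_rate * math.exp(
        params.beta1 * state.cumulative_miles + params.beta2 * state.recent_events
    )


def monthly_driving(state: DriverState, params: ModelParameters) -> float:
    """Monthly driving ``driving_need + beta3*R``, clamped at zero miles."""
    return max(0.0, params.driving_need + params.beta3 * state.recent_events)


def step(state: DriverState, params: ModelParameters, dt: float) -> DriverState:
    """One explicit-Euler step of length ``dt`` months.

    Flows are evaluated at the incoming state: new events are the risky-
    perceived share of events per month (rate x exposure), old events drain
    the recent stock at rate ``R / event_decay_time``.  The recent-events
    stock is clamped at zero (a large outflow cannot overshoot into negative
    event counts).
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    rate = events_per_mile(state, params)
    driving = monthly_driving(state, params)
    new_events = rate * driving * params.risky_fraction
    old_events = state.recent_events / params.event_decay_time
    recent = max(0.0, state.recent_events + dt * (new_events - old_events))
    return DriverState(
        recent_events=recent,
        cumulative_miles=state.cumulative_miles + dt * driving,
        time=state.time + dt,
    )


def simulate_driver(
    params: ModelParameters,
    config: SimulationConfig = SimulationConfig(),
    driver_id: str = "sim",
) -> Trajectory:
    """Simulate one driver over ``config.horizon`` calendar months.

    Reported monthly series are the latent deterministic ones: events per
    month (all events, before the risky-perceived filter) and miles per
    month.  With sub-monthly ``dt`` the sub-step flows are summed within each
    calendar month.
    """
    ev, mi, _, _ = simulate_cohort_paths(
        beta1=np.array([params.beta1]),
        beta2=np.array([params.beta2]),
        beta3=np.array([params.beta3]),
        event_decay_time=np.array([params.event_decay_time]),
        risky_fraction=np.array([params.risky_fraction]),
        driving_need=np.array([params.driving_need]),
        initial_event_rate=np.array([params.initial_event_rate]),
        initial_recent_events=np.array([config.initial_recent_events]),
        initial_cumulative_miles=np.array([config.initial_cumulative_miles]),
        months=config.horizon,
        steps_per_month=config.steps_per_month,
    )
    return Trajectory(
        driver_id=driver_id,
        months=np.arange(1, config.horizon + 1),
        events=ev[:, 0],
        miles=mi[:, 0],
    )


def simulate_cohort_paths(
    beta1,
    beta2,
    beta3,
    event_decay_time,
    risky_fraction,
    driving_need,
    initial_event_rate,
    initial_recent_events,
    initial_cumulative_miles,
    months: int,
    steps_per_month: int = 1,
):
    """Vectorised Euler simulation of D drivers at once.

    All parameter arguments broadcast to a common driver dimension D.
    Returns ``(events, miles, recent, cumulative)``: the first two are
    (months, D) per-calendar-month flows, the last two the (months+1, D)
    stock paths at month boundaries.  This is the computational core shared
    by the public simulator, the calibration objective and the synthetic
    generator; it deliberately avoids per-step Python object creation.
    """
    b1, b2, b3, tau, frac, need, rate, r0, c0 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (
            beta1, beta2, beta3, event_decay_time, risky_fraction,
            driving_need, initial_event_rate,
            initial_recent_events, initial_cumulative_miles,
        ))
    )
    d = b1.shape
    dt = 1.0 / steps_per_month
    recent = r0.astype(float).copy()
    cum = c0.astype(float).copy()
    events = np.empty((months,) + d)
    miles = np.empty((months,) + d)
    recent_path = np.empty((months + 1,) + d)
    cum_path = np.empty((months + 1,) + d)
    recent_path[0] = recent
    cum_path[0] = cum
    for m in range(months):
        ev_m = np.zeros(d)
        mi_m = np.zeros(d)
        for _ in range(steps_per_month):
            epm = rate * np.exp(b1 * cum + b2 * recent)
            driving = np.maximum(0.0, need + b3 * recent)
            ev_flow = epm * driving
            ev_m += ev_flow * dt
            mi_m += driving * dt
            recent = np.maximum(
                0.0, recent + dt * (ev_flow * frac - recent / tau)
            )
            cum = cum + dt * driving
        events[m] = ev_m
        miles[m] = mi_m
        recent_path[m + 1] = recent
        cum_path[m + 1] = cum
    return events, miles, recent_path, cum_path
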