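# Methods

## The model

`teendrive` implements a deterministic stock-and-flow model of how a newly
licensed teenage driver's rate of risky-driving events (hard braking /
acceleration, near-crashes, crashes captured by an in-vehicle recorder)
evolves month by month. Two stocks carry the state:

* **R(t)** — *recent events*: events still salient to the driver. New events
  flow in; events "age out" with a mean residence time τ (the *event decay
  time*, months).
* **C(t)** — *cumulative miles driven*: total exposure since licensure,
  fed by monthly driving.

Two behavioural laws close the loops:

```
events per mile:  e(t) = e0 · exp(β1·C(t) + β2·R(t))        β1, β2 < 0
monthly driving:  m(t) = max(0, N + β3·R(t))                β3 < 0
```

`e0` (*initial event rate*, events/mile at C = R = 0) and `N` (*driving
need*, miles/month at R = 0) vary per driver; β1, β2, β3 and τ are shared
across drivers. The auxiliary *events per month* is the dimensionally
consistent closure `E(t) = e(t) · m(t)`; a fraction `f` of events (the
*fraction perceived as risky*, default 0.07 — collisions) feeds the
recent-events stock:

```
R(t+dt) = max(0, R(t) + dt·( f·E(t) − R(t)/τ ))
C(t+dt) = C(t) + dt·m(t)
```

Integration is explicit (forward) Euler with flows evaluated at the
start-of-step state. `dt` defaults to 1 month — the observation cadence,
which is short relative to the ~6-month feedback delay — and may be any
1/k month; monthly reports then sum the sub-steps. The clamps on R and m
keep both stocks physically meaningful (β3 < 0 can otherwise drive
negative mileage). With `f = 0` and `R(0) = R0` the discrete solution is
`R0·(1 − dt/τ)^(t/dt)`, converging to `R0·e^(−t/τ)` as dt → 0; the test
suite checks 1% agreement at dt = 1/64.

Reported *events per month* is the all-events auxiliary `E(t)`, not the
risky-perceived subset, because observed panels count all recorded events.

## Synthetic cohorts

Real panels of this kind (n = 47 drivers, 5 months, events + odometer
miles) are generally not public, so the package ships a generator whose
defaults emulate the reference cohort's published monthly summaries:

| quantity | default | rationale |
|---|---|---|
| drivers × months | 47 × 5 | study design |
| β1, β2, β3, τ | −0.00025, −0.00800, −3.40216, 6.15949 | published estimates |
| f (collision share) | 0.07 | published share of events that are collisions |
| driving need `N_i` | lognormal, mean 925, sd 275 mi/mo | observed miles ≈ 550–630 (mean) after the β3·R offset |
| initial rate `e0_i` | lognormal, mean 0.130, sd 0.123 ev/mi | cohort-mean events/mile ≈ 0.05 at month 2 |
| initial stock R(0) | 126 events (point mass) | places the cohort-mean event-rate peak at month 2 |
| events noise | Poisson around the latent monthly events | threshold-crossing counts |
| miles noise | mean-one lognormal, sd 5% | odometer/reporting error |

Events are drawn Poisson around the *latent* trajectory (rate × latent
miles): reporting noise on miles does not change actual exposure. Each
event is flagged a collision with probability `f` (binomial thinning). The
generating truth (per-driver parameters) is always returned — the module
exists for recovery experiments.

Two features of the published summaries are **not** reproducible by this
model at the published parameter values, and the generator does not
pretend otherwise. First, the printed mean events/mile jumps 0.03 → 0.05
from month 1 to 2 (+67%); with τ ≈ 6.2 months the recent-events stock
decays too slowly for any admissible `R(0)` to produce more than a few
percent rise while keeping monthly miles in the printed range (larger
`R(0)` pushes the peak to month 3 and inflates the miles trend). The
defaults therefore place a genuine but shallow peak at month 2
(≈ 0.047 → 0.048 → 0.047). Second, mean events decline after month 2 in
the printed table but rise mildly in the model (miles growth outpaces the
rate decline) — consistent with the study's own finding that most of its
error is variance/covariance, not bias. Tuning used the
heterogeneity-weighted cohort mean, because high-rate drivers replenish
their recent-events stock faster and would otherwise shift the peak.

The rate-heterogeneity sd sits at the low end of the printed dispersion:
heavier tails make the cohort-mean rate ordering statistically
unidentifiable at n = 47 (the printed parentheticals are labelled SE but
have SD-like magnitudes; they are treated as cross-driver SDs).

## Calibration

Shared parameters (β1, β2, β3, τ) and per-driver parameters (`N_i`,
`e0_i`; optionally `R_i(0)`) are estimated jointly by minimising one pooled
objective: the mean of squared errors of simulated vs observed events/month
and miles/month, each series' errors divided by that observed series'
population variance so the ~500 mi/month scale cannot drown the ~20
events/month scale. `f` is held at 0.07. Simulation blow-ups return a large
finite penalty. Box bounds: β1 ∈ [−0.002, 0], β2 ∈ [−0.05, 0],
β3 ∈ [−20, 0], τ ∈ [0.1, 24] months, `N` ∈ [0, 3000] mi/mo,
`e0` ∈ [10⁻⁴, 1.5] ev/mi.

The optimiser is a multi-start derivative-free search. Given the shared
block the objective separates across drivers, so each evaluation of a
shared candidate *profiles out* the per-driver blocks: a coarse joint grid
over each driver's box (immune to the plateaus that appear when a
candidate collapses driving to zero), plus a moment-matching candidate
built from that driver's observed series, followed by damped Gauss-Newton
on the two best basins — all drivers advanced simultaneously with
vectorised 2×2 solves. The shared block itself is minimised by Powell's
conjugate-direction method with bounded golden-section line searches.
`n_starts` (default 200) points are sampled uniformly within bounds — the
per-driver coordinates keyed to driver ids, making results independent of
panel ordering — briefly searched, and the best few polished to a relative
objective tolerance of 10⁻¹⁰. Everything is deterministic given the seed.
On noise-free panels the search recovers the generating parameters to
~10⁻⁵ relative error (objective ~10⁻¹²).

An aggregate mode fits the driver-averaged series as a single
pseudo-driver. Confidence intervals come from a driver-level bootstrap
(resample drivers with replacement, recalibrate, percentile 2.5/97.5).

### What recovery experiments can and cannot show

At the study design — 47 drivers, 5 monthly observations, ~25 events per
driver-month — β1 is well identified (cross-driver exposure contrast), but
(β2, β3, τ) lie along a nearly flat ridge: on clean data, forcing τ from
6.16 to 8.0 months and re-optimising everything else raises the objective
by ~3·10⁻⁴, far below the ~10⁻²-scale noise floor of a Poisson-noised
panel. Least-squares estimates therefore wander along this ridge from seed
to seed (τ roughly 4–10 months), even though the optimiser verifiably
reaches the global minimum. Medians over ten cohorts land within ~10% of
the generating values but not inside the very narrow published intervals
(whose construction method is unstated). This is a property of the design,
not of the optimiser; passing noise-free exactness plus noisy scatter is
exactly the behaviour the theory predicts.

## Fit diagnostics

For each actual/simulated series pair the package reports RMSE, MAPE
(mean over points of |actual − simulated|/|actual| × 100; zero-actual
points are excluded and counted) and the Theil inequality decomposition
with population (1/n) standard deviations:

```
MSE = (S̄ − Ā)² + (s_S − s_A)² + 2(1 − r)·s_S·s_A
Um  = bias share   Us = variance share   Uc = covariation share
```

The covariation term is computed as the exact remainder
`MSE − bias − variance`, which is algebraically identical and immune to
the catastrophic cancellation of `1 − r` for near-perfectly correlated
series; the three shares then sum to one by construction. A perfect fit
(MSE = 0) reports the shares as undefined (`None`) rather than 0/0. The
panel-level report gives per-driver statistics and their cross-driver mean
and SD for events/month and driving/month.

## Numerical and design choices

* Flows at the pre-step state (explicit Euler), matching the model's own
  difference-equation formulation; no adaptive integration.
* The initial recent-events stock is configurable and calibratable but not
  free by default; recovery experiments pass the generator's value, since
  the observed 5-point series cannot separate it from the decay time.
* Driver blocks may only contain `driving_need`, `initial_event_rate`,
  `initial_recent_events`; the partition must cover all model constants
  and be disjoint.
* Bootstrap replicates that fail to calibrate are dropped and counted;
  more than half failing is an error.
* Panel CSVs are validated strictly (unique driver-month, contiguous
  months from 1, non-negative values); event rate is derived, never
  stored, with NaN marking zero-mile months.
* Configuration is YAML with unknown-key rejection; a reference file with
  every default ships with the package.
* Acceptance-scale experiments use 200 starts × 10 cohorts, a deliberate
  desk-scale analogue of the study's 648,265 searches over a ~100-parameter
  space; the profiled search reaches the same optimum from far fewer
  starts because each start already solves the per-driver subproblems.

## Limitations

* The generator emulates monthly panel summaries, not trip-level g-force
  data; within-month dynamics, weather/seasonality and driver dropout are
  out of scope.
* Only collisions feed the risky-perception loop, at a fixed 7%; real
  perception is surely richer.
* The per-driver lognormal heterogeneity is independent across need and
  rate; correlated heterogeneity (e.g., high-mileage cautious drivers) is
  not modelled.
* Tests passing on synthetic data show internal consistency (the pipeline
  recovers what the generator encodes, where identifiable); they cannot
  validate the model against real driving behaviour.
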