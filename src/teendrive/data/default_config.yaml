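parameters:
  beta1: -0.00025
  beta2: -0.008
  beta3: -3.40216
  event_decay_time: 6.15949
  risky_fraction: 0.07
  driving_need: 925.0
  initial_event_rate: 0.13
simulation:
  dt: 1.0
  horizon: 5
  initial_recent_events: 126.0
  initial_cumulative_miles: 0.0
generator:
  n_drivers: 47
  months: 5
  need_distribution:
    mean: 925.0
    sd: 275.0
  rate_distribution:
    mean: 0.13
    sd: 0.123
  initial_recent_events: 126.0
  noise:
    poisson_events: true
    miles_sd: 0.05
  seed: 0
optimizer:
  n_starts: 200
  seed: 0
  max_iter: 60
  tolerance: 1.0e-10
  explore_iter: 2
  n_polish: 3
seed: 0
log_level: INFO
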