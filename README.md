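# postcapture

Post-capture movement, space use, and survival analysis for GPS-collared
ungulates.

Wildlife captures (drop nets, helicopter net-guns) disturb the animals they
instrument: movement is suppressed for days after release, and a small
fraction of animals die of capture-related causes within the first month.
Telemetry studies need to know how long that disturbance lasts — both to
report welfare outcomes and to decide how many post-capture days to censor
before analysis. This package implements the full assessment workflow for
30-minute GPS collar data over a 31-day post-capture window (capture day 0
plus 30 days), for researchers in movement ecology and wildlife management:

* **synthetic cohorts** (`postcapture.simulate`) — home-ranging movement
  from a discrete Ornstein–Uhlenbeck process,
  x_{t+Δ} = c + φ(x_t − c) + ε, φ = exp(−Δ/τ), ε ~ N(0, σ²(1−φ²)I),
  with method-specific release translocation, post-release step
  suppression of known duration, mortality (stationary-collar emission),
  GPS artifacts, and a truth table for validation;
* **trajectory cleaning** (`postcapture.telemetry`) — UTC→local time,
  resampling to the 30-minute schedule, step metrics (distance, velocity,
  net displacement, heading, turning angle), censoring of teleports
  (>32 km from the median location) and out-and-back spikes (≥2 km from
  both 30-minute neighbours), stationary-cluster end-date detection, and
  movement/survival eligibility windows;
* **daily metrics** (`postcapture.metrics`, `postcapture.spaceuse`) —
  daily distance traveled, mean daily displacement from the day-1 anchor,
  99% kernel daily range (reference bandwidth h = 0.5(sd_x+sd_y)n^(−1/6),
  100-m grid, 1 cell = 1 ha), and consecutive-day range overlap (Jaccard);
* **capture-effect inference** (`postcapture.capture_effect`,
  `postcapture.lmm`, `postcapture.transforms`) — Yeo–Johnson / Ordered
  Quantile normalization, a Gaussian random-intercept mixed model with
  day-since-capture (reference = each animal's 30-day long-term mean),
  method, sex, their interactions, and season as a blocking factor; Wald
  type-III χ² tests; day-vs-baseline EMM contrasts; and the altered-day
  span rule with single-day bridging;
* **survival** (`postcapture.survival`) — Kaplan–Meier with Greenwood
  variance, Cox proportional hazards (Efron ties, Newton–Raphson),
  Harrell's C-index, and the scaled-Schoenfeld proportional-hazards test.

The `analysis/` scripts chain these stages on a simulated study-scale
cohort (192 deployments), and `postcapture.study` carries the published
count table of a white-tailed deer capture study (190 capture events,
13 mortalities) whose survival estimates the package reproduces exactly.

## Worked example

```sh
cd analysis
python 01_simulate_cohort.py   # 192 deployments, truth table
python 02_clean_trajectories.py
python 03_movement_metrics.py
python 05_capture_effect.py
python 06_survival.py
```

The metrics stage prints the per-method long-term means of the simulated
herd (meters/day):

```
long-term mean distance (m):     {'drop_net': 2599, 'single_helicopter': 2044, 'tandem_helicopter': 2336}
long-term mean displacement (m): {'drop_net': 685,  'single_helicopter': 1541, 'tandem_helicopter': 515}
```

Drop-net animals travel normally from day 1 (they are released where they
were caught); single-helicopter animals show the largest displacement
because they were translocated 0.5–3.1 km to a processing station. The
capture-effect stage then recovers the simulated suppression durations
from the fitted day × method contrasts:

```
== distance (yeo_johnson transform) ==
  day:method       chi2= 2055.57 df= 60 p=0.0000*
  altered span [drop_net]: 0 days
  altered span [single_helicopter]: 9 days
  altered span [tandem_helicopter]: 5 days
```

i.e. daily distance differed significantly from each animal's long-term
mean for 9 days after single-helicopter capture and 5 days after tandem
capture, exactly the durations the generator injected. The survival stage
reports the simulated cohort (`S(31) = 0.90 ± 0.02 SE` from 20 detected
mortalities of 192 collars) and the published-count reproduction:

```
S(31): overall 0.93 ± 0.02, drop net 0.90, single 0.94, tandem 0.94
mortality: 6.8% overall = 1.6% direct + 5.3% post-release
```

## Command-line interface

`postcapture` exposes the stages as subcommands over a YAML config:
`simulate`, `clean`, `metrics`, `spaceuse`, `capture-effect`, `survival`,
`report`, and `run-all`. Every run directory carries a manifest of config
and output hashes; reruns with the same config are byte-identical and
resume from completed stages.
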