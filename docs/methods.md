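# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of the package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Study design emulated by the generator

A deployment is one collar-on-animal episode. Day 0 is the local calendar
day of capture; days 0–30 form the survival window ("31-day study
period") and days 1–30 the movement window (capture-day data are censored
because capture times vary). A deployment is movement-eligible only if
every day 1–30 carries ≥90% of the expected 48 fixes and no end-of-data
was detected inside the window; it always contributes to survival, as an
event if an end-of-data day was detected in days 0–30, otherwise censored
at day 31 (or at its last data day if the collar stopped early). Capture
seasons are meteorological (spring = Mar–May, …); for survival modeling
they collapse to a thermal pair, warm = summer versus cool = the rest.

## Movement model

Positions follow a stationary, isotropic Ornstein–Uhlenbeck (OU) process
around an activity center c — the simplest home-ranging process with
range fidelity. Sampled every Δ = 30 min,

    x_{t+Δ} = c + φ (x_t − c) + ε_t,   φ = exp(−Δ/τ),
    ε_t ~ N(0, σ² (1 − φ²) I),

so the stationary positional SD per axis is σ. Innovations are scaled by
a per-deployment-day lognormal activity multiplier (sd of log = 0.35,
mean 1) and a seasonal multiplier (spring 0.85, summer 1.0, autumn 1.3,
winter 1.0). The daily multiplier is essential, not cosmetic: a pure OU
path at 48 fixes/day has a day-to-day coefficient of variation of daily
distance of only ≈7% (a sum of 48 near-independent step lengths), far
below what free-ranging ungulates show, and without realistic day-level
variability every post-recovery day would differ "significantly" from the
long-term mean and the altered-day rule would be vacuous.

### Calibration of the defaults

The defaults σ = 410 m, τ = 96 h were fixed once against the long-term
marginal means the emulated study design targets: mean daily distance
≈2.4–2.8 km and long-term displacement ≈0.6–0.9 km (the simulated herd
reproduces both; see `analysis/03_movement_metrics.py`). Expected daily
distance is 48 · √(π/2) · σ√(1−φ²) per the Rayleigh step-length mean.

A position-OU process cannot simultaneously reproduce the target daily
distance and daily 99% kernel ranges of hundreds of hectares: once the
step scale is pinned by the distance target, the within-day positional
spread saturates (≈35–40 ha at any τ) because the path is diffusive
rather than persistent. Real deer paths are directionally persistent at
sub-hour scales, which spreads the same daily distance over a much larger
area. A correlated-velocity process would fix this but is deliberately
out of scope; consequently simulated daily ranges (~32 ha) and overlaps
(~0.26) are smaller than field values, and tests validate the space-use
estimators against analytic oracles (Gaussian isopleth areas, closed-form
kernel mass) rather than against absolute field-scale range sizes.

### Capture effect

The release point is displaced from the activity center by a uniform draw
in the method's translocation range (drop net 0 km; tandem helicopter
0–0.5 km; single helicopter 0.5–3.1 km), direction uniform. For the
configured number of full days after the capture day (defaults: single 9,
tandem 5, drop net 0) step innovations are multiplied by the suppression
factor (default 0.3) while mean reversion keeps pulling the animal toward
its activity center, producing both reduced daily distance and a gradual
return to the established range. The suppression magnitude is not
reported by field studies; 0.3 was chosen as a strong-but-plausible
response and is a config field, not a constant.

### Mortality and artifacts

With probability 13/190 (the emulated study's mortality fraction) a death
day is drawn uniformly in days 0–29 and all later fixes are replaced by a
fixed point plus 10 m GPS noise. Collar drop and death are deliberately
indistinguishable, as they are to the real detector. Artifacts are built
to trigger each censoring rule: teleports placed 33–100 km from the
trajectory median, and out-and-back spikes 2.5–8 km from the true
position between intact 30-minute neighbours.

## Cleaning conventions

* Resampling keeps the fix nearest each local :00/:30 slot within ±3 min,
  ties to the earlier fix; it is idempotent.
* Rule A censors fixes >32 km (planar) from the component-wise median
  location. Rule B censors fix i when both neighbour distances are ≥2 km,
  both time gaps ≤30 min, and the neighbours are within 2 km of each
  other — the last clause protects genuine fast transits. Rules run once
  each, in that order.
* End-of-data detection scans forward windows of 48 h and flags the first
  window whose fixes all lie within 45 m of the window centroid. The
  45 m/48 h defaults were chosen so that a dead collar (10 m GPS noise)
  is detected in the first window with probability ≈0.97 while a living
  animal under strong movement suppression (factor 0.3) almost never
  qualifies; a 24-h window at the same radius would misclassify a
  substantial share of suppressed-but-alive deployments. Both parameters
  are exposed.
* Heading is measured clockwise from north; turning angles wrap to
  (−180°, 180°]; the first fix's step quantities are NaN, never zero.

## Daily metrics

Daily distance sums step lengths whose starting fix falls in the local
day (midnight boundaries; a midnight-crossing step belongs to its
starting day). Daily displacement averages the Euclidean distance from
each of the day's fixes to a fixed anchor, the deployment's first
retained fix of day 1. The anchor is fixed (not per-day) because the
quantity of interest is how far animals settle from their release sites;
a per-day anchor is available via `daily_displacement(..., anchor=...)`.
Each eligible deployment's long-term mean is the arithmetic mean of its
30 daily values (29 for overlap) and enters the model as one extra
reference row.

Daily ranges use an isotropic Gaussian KDE with the classical ad hoc
reference bandwidth h = 0.5(sd_x + sd_y) n^(−1/6) (sample SDs, n−1
denominator; floor 25 m for degenerate inputs), evaluated at the centers
of a 100-m grid snapped to absolute multiples of the cell size and padded
3h beyond the fix bounding box, normalized to unit mass. The 99% isopleth
is the smallest prefix of density-sorted cells reaching 99% of the mass
(ties at the cut included); area is the cell count, exactly 1 ha per
cell, avoiding polygon-simplification drift. Overlap between consecutive
days defaults to the Jaccard index on the (automatically aligned) cell
sets; the directional variant area(A∩B)/area(A) is a config option. The
union denominator is symmetric and conservative; 30 consecutive daily
ranges yield exactly 29 overlap values.

## Capture-effect inference

Responses are normalized before modeling: daily distance by Yeo–Johnson
(λ by profile maximum likelihood over [−5, 5], via the standard piecewise
power family), the other metrics by the Ordered Quantile map
x → Φ⁻¹(rank/(n+1)) with midranks for ties, linear interpolation inside
the training range on the normal-quantile scale, and linear tail
extrapolation. Both transforms are invertible on the training range;
back-transformed marginal means apply a second-order Taylor bias
correction using the total random variance σ²_b + σ²_e (a smearing
estimator would be the nonparametric alternative).

The model is a Gaussian linear mixed model with a random intercept per
deployment: day-since-capture (31 levels, the long-term mean as the
reference level), capture method (3), sex (2), all their interactions,
and capture season (4) as a blocking factor. The long-term-mean rows
share their deployment's random intercept with its daily rows, since both
derive from the same animal. Fitting profiles the deviance over the
variance ratio γ = σ²_b/σ²_e and solves generalized least squares in
closed form at each γ via per-group mean shrinkage; ML is the default
(REML available, and on balanced one-way designs REML reproduces the
ANOVA method-of-moments components exactly — the ML components carry the
usual (G−1)/G shrinkage). All factors use sum-to-zero coding, so the
type-III Wald test of a term is the block χ² on its coefficient rows.
Inference is z/χ² asymptotic — no Kenward–Roger or Satterthwaite small-
sample correction — which is appropriate at the ≈5,000-row design size
this stage targets.

Estimated marginal means average model predictions over non-focal factor
levels with equal weights (the reference-grid convention). Day-vs-
reference contrasts are computed within each method (and within
method × sex when the three-way interaction is significant at α = 0.05)
with delta-method SEs and unadjusted z p-values — a treatment-vs-control
screen, not a familywise procedure. Seasonal EMM contrasts are adjusted
by the studentized-range (Tukey) method for k = 4 means in the large-df
limit.

### The altered-day span rule

Scanning from day 1, the span extends while days differ significantly
from the long-term mean **in the direction of the day-1 response**; one
embedded non-significant day is bridged when the following day is again
significant in that direction; significant days beyond the span are
reported as artifact days (daily variation, not capture effect); a
non-significant day 1 means span 0. The sign condition is a deliberate
design choice: the long-term mean includes the suppressed days, so after
recovery every normal day sits systematically *above* it — with a 9-day
suppression at factor 0.3 the baseline is depressed ≈21% and, at cohort
sample sizes, post-recovery days are routinely significantly positive.
Without the sign condition the span would absorb the entire recovery
plateau; with it, the rule tracks the initial post-capture deviation and
recovers injected suppression durations of 0/2/5/9 days within ±1 day in
the end-to-end tests.

## Survival

Records are (time, event) with covariates method, sex, thermal season.
The Kaplan–Meier estimator processes deaths before censorings at tied
times, uses Greenwood's variance, and log-scale 95% CIs. The Cox model
maximizes the Efron-tie partial likelihood by Newton–Raphson with step
halving (relative log-likelihood tolerance 10⁻⁹, max 50 iterations);
day-0 deaths are shifted to time 0.5 so they contribute risk sets
(Kaplan–Meier ranking is unaffected); diverging coefficients (monotone
likelihood/separation) are flagged with a warning rather than silently
penalized. Harrell's C counts risk-score ties as one half, with a
delete-one jackknife SE over subjects. The proportional-hazards check
regresses scaled Schoenfeld residuals (Efron-weighted risk-set means at
tied times) on the Kaplan–Meier-transformed time axis — g(t) = KM
survival at the event time, right-continuous, the convention of the
standard survival toolchain — giving per-covariate df-1 score tests and a
global test on all coefficients. Calibration note: the global test holds
its nominal size in event-rich designs (~95% events) and becomes
conservative under heavy censoring; the calibration test uses an
event-rich null design for that reason.

## Problem sizes used by the test suite

The end-to-end recovery check simulates 20 cohorts of 120 deployments
(40 per method, suppression {0, 2, 5, 9} days at factor 0.3) and requires
spans within ±1 day in ≥80% of method-level fits, plus the qualitative
displacement ordering (single helicopter > drop net and tandem). The
type-I-error checks run 1,000 null replicates each: a 40-group × 9-row
LMM for the mixed-model Wald test, and a 300-subject exponential-survival
design for the Cox Wald and global Schoenfeld tests, asserting empirical
size in [0.03, 0.07] at α = 0.05. The analysis drivers use a 192-
deployment cohort, matching the emulated study's 190 capture events.

## Known limitations

* Position-OU movement underestimates daily range area and overlap at a
  fixed daily distance (see Calibration); range/overlap conclusions from
  the simulator are qualitative.
* The spike-censoring rule is a formalization of an informally described
  field practice ("locations ≥2 km from an established cluster"); the
  d(i−1, i+1) < 2 km clause is this package's definition.
* One UTC offset per deployment; no daylight-saving transitions or
  multi-timezone trajectories.
* Collar drop and mortality are indistinguishable by design, so detected
  "mortalities" are an upper bound on true deaths.
* No frailty terms, time-varying covariates, or competing risks in the
  survival stage; no LSCV/plug-in bandwidths or utilization-distribution
  overlap indices (BA, UDOI) in the space-use stage.
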