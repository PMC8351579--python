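# Methods

## Problem and data model

The package estimates the power of short human listening surveys to detect a
chorusing amphibian, using continuous recordings from automated recorders as
ground truth. The atomic unit is the 5-minute *interval*: a (site, date,
bin-start) cell scored 1 if at least one verified vocalization event longer
than 3 s overlaps it, else 0. Bins are calendar-aligned to the clock
(hh:00, hh:05, …) and half-open, so they are site-independent and an event
spanning a boundary marks every bin it touches — a surveyor present in either
window would have heard the call. The 3-s floor (`min_event_s`, configurable)
reflects that very short classifier detections are overwhelmingly false
positives; exactly-3-s events are excluded (strict `>`). An interval belongs
to the calendar date containing its bin start, so one night contributes
morning bins to one date key and evening bins to the previous one; all date
logic (eligibility, one-survey-per-date) keys on calendar dates because
surveys are scheduled per date from forecasts.

Binning requires an explicit *coverage* table enumerating every bin the
recorder actually ran: non-recording time is absent rows, never zeros, and
events falling wholly outside coverage are dropped with a warning.

## Derived weather features

From hourly observations (temperature °C, relative humidity %, wind km/h,
barometric pressure, hourly precipitation mm) two look-back features are
derived:

* `pressure_change_24h(t) = pressure(t) − pressure(t − 24 h)`, defined only
  when both endpoints exist;
* `cum_precip_24h(t)` = sum of hourly precipitation over the *preceding* 24
  hours, window `[t − 24 h, t)` — the current hour is excluded because the
  feature describes rain that has already fallen — defined when at least 18
  of the 24 window hours (75%) were observed.

Both are missing (NaN) throughout the first 24 h of a series and near gaps;
a missing feature never satisfies a threshold rule, which avoids spurious
eligibility from absent data. Pressure is carried in the station's native
unit without conversion (the motivating dataset labels mmHg but tabulates
values consistent with inHg); thresholds must simply be expressed in the same
unit. Moon illumination is a per-date fraction in [0, 1]; readers
auto-detect percent input, and condition summaries report percent.

Detection-night condition summaries (min/Q1/median/mean/Q3/max per variable)
are computed over *all* hourly observations on detection-positive dates, not
only night hours, matching the whole-calendar-date eligibility semantics.
All quantiles in the package use linear interpolation between order
statistics.

## Scenarios and eligibility

A scenario is: a month set (default Feb–Apr), a nightly window (default
before 06:00 or at/after 18:00, applied to bin starts), and threshold rules
over {temp_c, rh_pct, wind_kmph, moon_illumination, pressure_change_24h,
cum_precip_24h}. A date is eligible iff at least one hourly observation
satisfies **all** rules simultaneously (moon treated as constant over the
date). The alternative semantics — each rule met at some, possibly different,
hour — is available as a flag (`simultaneous=False`); simultaneous is the
default because it matches how a surveyor experiences conditions on site.
Eligibility is monotone: adding a rule can only shrink the eligible set.

The USFWS preset's moon threshold is 0.5 as a *fraction* (half illuminated):
read as 0.5% it would leave essentially no eligible dates, contradicting the
protocol's intent of merely avoiding bright-moon nights.

## Survey simulation

For a pool of eligible intervals and a survey length of `k` five-minute bins,
one permutation simulates a season: every date receives exactly one survey,
drawn uniformly over its valid starts, and the detection-probability estimate
is (positive surveys) / (dates surveyed). Sampling one survey per date
removes within-date pseudo-replication, mirroring field practice. Default
1,000 permutations; the mean and 2.5/97.5% quantiles of the estimates
summarize each (scenario, duration) cell.

A survey is by default a *contiguous* k-bin window at a single site with no
temporal gap (a surveyor stays at one listening post); the window is positive
if any constituent bin is. When both sites have valid starts on a date the
draw is over their union, so a site's selection probability is proportional
to its capacity. Dates whose contiguous capacity is below `k` are dropped
from that duration's simulation with a warning, not padded. An alternative
`independent` mode draws `k` distinct bins without replacement anywhere in
the date's night; it is implemented as an exact per-date Bernoulli with
probability `1 − C(neg, k)/C(total, k)`, which is identical in distribution
to explicit sampling.

Because the estimate averages independent uniform per-date draws, its exact
expectation is the mean over dates of (positive starts / valid starts);
`analytic_mean` computes this closed form and serves as the simulator's
oracle in the tests (agreement within 4 Monte-Carlo standard errors). The
expectation is provably non-decreasing in `k` on a fixed date set: widening a
window can only add positive bins.

All randomness flows from `numpy.random.default_rng` seeded per call;
identical seeds give bit-identical estimate vectors. The effort grid spawns
one child seed per cell from a single `SeedSequence` root.

## Minimum survey effort

`N_min = ceil(log(1 − C) / log(1 − p))` at confidence `C` (default 0.95).
Ceiling rounding implements "at least N surveys"; a 1e-9 slack absorbs
floating-point noise when the ratio lands on an integer. `p ≥ 1` needs one
survey; `p ≤ 0` is an error — absence can never be confirmed — and effort
cells with a zero probability estimate carry NaN counts with a warning
rather than aborting a whole grid. In the effort table the *low* survey
bound pairs with the *upper* probability quantile and vice versa; because
the bounds are computed from rounded quantiles of p rather than quantiles of
per-permutation N, bound integers can differ by ±1 from tabulations that
applied the formula to unrounded probabilities.

## Threshold search

The search scores a rule combination by the detection:non-detection ratio of
the intervals it leaves surveyable (∞ if no negatives remain, undefined if
nothing remains). Candidates per variable are the unique observed values,
optionally decimated to at most `resolution` quantile points; both directions
(`>`, `<`) are tried per candidate, and the full Cartesian product of one
choice per variable is enumerated. Ranking is ratio-descending with total
tie-breaking (larger positive count, then more dates, then lexicographic rule
order), so output is deterministic. A `min_dates` floor (default 0) guards
against degenerate optima concentrated on a handful of dates. No
train/test split is performed — the ranked thresholds describe the searched
dataset and are optimistically biased out of sample; the synthetic module
supports fresh-seed out-of-sample evaluation.

## Synthetic data

The generator emulates a multi-year, two-site continuous deployment
(Jan 1–Jul 31 per year):

* **Temperature**: annual cosine (mean 20 °C, amplitude 9 °C, coldest
  mid-January) + diel cosine (amplitude 4 °C, peak 15:00) + AR(1) noise
  (φ = 0.9, σ = 1.2 °C).
* **Rain**: each date rains with probability 0.22; event totals are
  gamma(0.9, 9 mm) spread over 1–5 consecutive hours with Dirichlet weights.
* **Humidity**: mean 72%, diel cycle anti-phased with temperature (±14%),
  +12% on rain hours, Gaussian noise, clipped to [0, 100].
* **Wind**: AR(1) around 8 km/h, clipped at 0.
* **Pressure**: mean-reverting random walk (step σ 0.02, reversion 0.02 per
  hour) around 29.5, giving 24-h changes on the ±0.1–0.3 scale that the
  falling-pressure threshold operates on.
* **Moon**: deterministic 29.53-day cycle from a fixed new-moon epoch.
* **Chorus**: per site-night, initiation is Bernoulli with logistic
  probability `σ(β₀ + β_T·T₂₂ + β_P·rain24 + β_dB·Δp24 + β_s·G(doy))`,
  where the conditions are read at 22:00 and `G` is a Gaussian breeding-
  phenology bump (peak day-of-year 75, sd 20 d). The phenology gate is
  biologically necessary: without it a purely weather-driven logistic would
  put peak chorusing on the warmest (summer) nights, which real spring-
  breeding toads do not do. Defaults: β₀ = −9.2, β_T = 0.12 /°C,
  β_P = 0.12 /mm, β_dB = −8.0, β_s = 9.4. An initiated night holds one
  (45%: two) contiguous bouts starting ~21:30 (sd 1.5 h), of geometric
  length (mean 50 bins ≈ 4 h), each bin detected with probability 0.92.
  Contiguous bouts are the load-bearing structural choice: within-night
  detections are strongly autocorrelated, so lengthening a survey adds
  less information than independent per-bin noise would suggest — the
  feature that shapes the detection-vs-duration curve.
* **Dropout**: each site-date is lost entirely with probability 0.03.

Defaults were calibrated once against the structural targets the analysis
assumes — a few percent of recorded bins positive (observed 2.5–3.1% across
held-out seeds), ≥95% of positives in February–April, positives confined to
a minority (~20%) of dates, and a planted environmental signal recoverable
by the threshold search — and are not tuned per test. What the synthetic
data does *not* emulate: classifier false positives/negatives (inputs are
assumed verified), site heterogeneity in abundance, multi-day recorder
outages, within-season population turnover, or any moon effect on chorusing
(deliberately absent, matching evidence that moonlight is not a driver for
this species — searches over moon thresholds on synthetic data should find
nothing). Passing tests therefore demonstrate the pipeline's statistical
machinery, not field realism of any particular parameter value.

`constant_rate_dataset` is the null-structure oracle: every bin independent
Bernoulli(q), so the k = 1 simulated mean must recover q and
`min_surveys(0.1) = 29` follows in closed form.

## Numerical and degenerate-input choices

* Quantile method: linear interpolation, used uniformly (summaries and
  permutation quantiles).
* Empty pools: error for simulation, empty-with-warning for summaries and
  searches; all-date-excluding rule sets yield an undefined-flagged ratio.
* Events exactly at the duration floor are excluded; events straddling
  midnight are attributed bin-by-bin to the calendar date of each bin.
* Duplicate timestamps, out-of-range humidity, negative durations, and
  off-grid bins are reader-level errors naming the offending line.
* The pipeline runs all stages under one root seed, records per-stage row
  counts and warnings in `manifest.json`, and contains no wall-clock state,
  so reruns are byte-identical.

## Problem sizes

The shipped defaults simulate 4 years × 2 sites (~475,000 intervals,
~20,000 weather hours); a full three-scenario, twelve-duration effort grid
at 1,000 permutations completes in seconds. Tests use these defaults plus
smaller single-year fixtures, and the planted-signal checks average over
five generator seeds.

## Known limitations

* Surveys never span two calendar dates; a run crossing midnight belongs to
  the morning date and is not joinable with the previous evening.
* Eligibility is station-global: no per-site weather.
* The grid search enumerates the full Cartesian product; with many variables
  or undecimated continuous candidates it grows combinatorially — use
  `resolution`.
* The effort formula assumes surveys are independent given presence;
  serially correlated chorusing across nights violates this mildly, in the
  direction of underestimating required effort.
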