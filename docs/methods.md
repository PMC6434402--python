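# Methods

## Data model

A subject-day is a fixed vector of 1440 minute slots on the local clock;
slot *k* holds the heart rate recorded in minute *k* or an explicit missing
marker (NaN). Present values must lie in [25, 250] beats/min; out-of-range
readings are rejected at ingest rather than clipped. Days are forced to 1440
slots regardless of daylight-saving anomalies (readings past slot 1439 are
dropped with a warning) — device exports rarely encode UTC offsets reliably,
and fixed-length days keep every downstream computation positional. Days
with zero recorded minutes are still materialized so compliance denominators
count them.

The study calendar lists the observed (year, month) pairs, half-open
excluded date ranges (breaks), named semester intervals, and the seasonal
period. The default calendar spans August 2015 – April 2017 with May–July
2016 withheld: 18 observed months, period 9 (one academic year), four
semesters. Optional per-subject enrollment windows let the cohort filter
skip semesters that ended before a subject joined.

## Compliance

Wear at a minute means "a heart rate was recorded at that minute"; no
off-wrist heuristic is layered on top, and wear time is always computed
before imputation. The daily threshold is `round(0.80 × 1440) = 1152`
minutes. The commonly quoted "19 hours" is the floor of 1152/60 — the
fraction is primary, so the threshold is 1152 and not 1140. Cohort selection
takes each subject's minimum over semesters of compliant-day counts and
requires it to be *strictly greater than* 49 ("above" the median); a `ge`
comparator is available since the original rule's strictness is ambiguous.
Days inside excluded break ranges never count toward semester totals.

## Imputation

Linear interpolation fills interior gaps of ≤ 150 min between the flanking
present values. Leading/trailing gaps have only one flank and stay missing;
so do over-long gaps. Imputed values are kept real-valued because the only
consumer is a threshold comparison — rounding to integer bpm would bias
minutes sitting near the zone boundary (display rounding is a config flag).
The operation never touches present values and is therefore idempotent.

The benchmark that justifies the choice deletes non-overlapping blocks of
exactly 25, 50, or 150 minutes from complete days, uniformly among feasible
positions, until missingness first reaches 20% (the last block may
overshoot), then scores RMSE pooled over all deleted minutes of all days.
Pooling (rather than averaging per-day RMSEs) weights every deleted minute
equally; the alternative changes results only at the second decimal on our
synthetic days. Day degradations are keyed by (subject, date, block) with a
CRC so the benchmark is reproducible and independent of input order.
Alternative imputers plug in as callables; only linear interpolation ships.

## Target zones and bouts

The Karvonen zone minimum is `(HRmax − RHR) × Y + RHR` with Y = 0.5.
Parameters are per subject-day: HRmax defaults to the age-predicted
`220 − age` (an explicit measured value overrides), and RHR comes from a
per-day input column when available, else from the day itself as the mean of
its 30 lowest recorded minutes — a deliberately simple estimator that tracks
slow RHR drift without modeling sleep. Zone membership is `HR ≥ zone_min`,
inclusive, with no upper cutoff; missing minutes are out of zone, imputed
minutes participate.

Bout detection is merge-then-filter by default: maximal in-zone runs are
combined across single-minute out-of-zone dips (left to right, so chains
collapse), then merged runs shorter than 10 elapsed minutes are discarded.
The bridged minute counts toward duration and target minutes (elapsed-time
convention). Both decisions have flags: `merge_before_filter=False` merges
only runs that already qualify, and `count_bridged=False` sums strictly
in-zone minutes. Merge-then-filter is the default because the dip being
forgiven is interpreted as a recording artifact *within* one continuous
effort, not as the boundary between two efforts. The detector is verified
exhaustively against a naive run/merge-fixpoint/filter enumerator.

## Trend extraction

Only compliant days contribute to monthly aggregation: the month's summed
target minutes over compliant days divided by the count of compliant days.
A month with zero compliant days is missing; interior missing months are
linearly interpolated before decomposition (flagged in the output), while
leading/trailing missing months shorten the series.

The classical additive decomposition is implemented directly so edge
behavior is explicit: the trend is a centered simple moving average of
window `period` (period 9 is odd; the first and last 4 positions are
undefined; a 2×MA convention covers even periods), the seasonal component is
the per-phase mean of the detrended series re-centered to zero, and the
remainder is what's left. `statsmodels`' implementation of the same
procedure serves as an independent cross-check in the test suite.

The Mann-Kendall statistic S is the sum of pairwise sign comparisons; its
variance uses the standard tie correction, and the p-value uses the normal
approximation with the ±1 continuity correction at every n (a warning is
logged below n = 10, where the approximation is crude). The test runs on the
trend component's defined positions only — 10 of 18 points at the defaults —
and labels are positive/negative when p < .05 with the matching sign of S,
else none. The Kruskal-Wallis balance check pools each subject's
compliant-days-per-month values into its label group and compares the three
group distributions with tie-corrected ranks.

### A statistical caveat that matters

Running Mann-Kendall on a moving-average-extracted trend violates the
test's independence assumption: adjacent trend values share 8 of their 9
inputs, so a trend extracted from a *driftless* noisy series behaves like a
short random walk, and the test rejects far above its nominal level. In our
simulations (zero-drift synthetic subjects, period-9 seasonality, the
default gap model, 200 subjects) roughly 40–55% of no-trend subjects receive
a spurious positive or negative label at α = .05, versus under 1% when the
test is applied to the raw 18-point normalized series. Because the test is
rank-based, no choice of noise scale changes this. The pipeline implements
the procedure as designed — the test on the extracted trend — and the test
suite records the inflated false-label rate rather than hiding it. Users who
need calibrated type-I error should either test the raw normalized series,
or use a trend test with an autocorrelation correction; labels from the
default procedure are best read as "detected monotone movement of the
smoothed profile", not as calibrated hypothesis tests. Power for genuinely
drifting subjects is excellent (≥ 90% recovery at ±1.5 min/day per month,
100% in our runs).

## Synthetic cohorts

The generator emulates exactly the structure the pipeline consumes:

* **Baseline** — one sinusoid per subject with random phase, trough at the
  subject's RHR (drawn N(62, 5²), clipped to [45, 85]), peak +25 bpm, plus
  N(0, 3²) noise. No sleep architecture, heart-rate variability, or
  activity outside bouts.
* **Bouts** — daily count ~ Poisson(expected/20), durations 10 + Poisson(10)
  minutes (capped at 90), scheduled 07:00–22:00 with ≥ 5-minute separations
  so ground-truth bouts never merge. In-bout HR sits 10–15 bpm above the
  subject's zone minimum with 3-minute sub-threshold ramps outside the
  interval, so with noise off the in-zone mask equals the scheduled
  intervals exactly.
* **Activity trend** — expected daily target minutes in observed month *i*
  are `30 + drift·i + seasonal[i mod 9]` (floored at 0), with the seasonal
  profile a zero-mean cosine of amplitude 5 min/day by default.
* **Missingness** — per day: with p = 0.02 the whole day is missing; with
  p = 0.08 a contiguous chunk of ≥ 300 minutes is deleted (guaranteeing a
  noncompliant day); otherwise Poisson(3) dropout gaps with lengths drawn
  uniform{2..25} (85%) or uniform{26..150} (15%), placed without overlap and
  with start odds tripled inside bouts to mimic dropout under exertion.
  Ground truth is recorded before deletion.

Seeding: a single global seed spawns per-subject `numpy` substreams keyed by
subject index, so cohorts are byte-reproducible and invariant to generation
order. What passing tests on this generator shows is that the *pipeline
machinery* is correct and that trend recovery works when the generating
process matches the pipeline's assumptions; it says nothing about sensor
bias, posture artifacts, medication effects, or real wear behavior, none of
which are modeled.

## Validation problem sizes

The parameter-recovery experiment used by the test suite and the
reproduction script runs 10 replicate cohorts of 60 subjects (20 per drift
arm at +1.5, −1.5, 0 min/day per month), pooling 200 labeled
subject-outcomes per arm — enough to estimate recovery rates to within a
couple of percentage points while keeping a full run to a few minutes on one
CPU. The imputation benchmark uses 30 complete synthetic days; bout-detector
oracle checks use 10 000 random masks up to length 200; the Mann-Kendall
oracle check is exhaustive over all 3 267 sequences of length ≤ 7 on a
3-letter alphabet.

## Known limitations

* The inflated false-positive rate of Mann-Kendall on smoothed trends,
  discussed above — inherent to the procedure, not to this implementation.
* `220 − age` is a crude HRmax proxy; the Karvonen zone inherits its error.
* The RHR fallback estimator is biased high on days with little sedentary
  time and is undefined below 30 recorded minutes.
* Loess-based detrending for aperiodic designs is a config hook only.
* The per-day data model splits midnight-spanning gaps and bouts at the day
  boundary; activity minutes around midnight can be undercounted.
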