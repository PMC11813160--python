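# Methods

## Scope and data model

The package processes minute-level wearable exports for free-living cohort
analysis. Four per-minute streams are consumed as the device reports them —
heart rate (bpm), steps, an intensity label in {sedentary, lightly,
moderately, very active}, and a sleep-stage label in {1 asleep, 2 restless,
3 awake}, with absence meaning "fully awake or device off". The package
does not re-derive any of these from raw signals; its contribution is the
cleaning, validation and summarization layer above them.

All timestamps are naive local civil time normalized to whole minutes. No
timezone or daylight-saving arithmetic is performed: clock time is taken
as-is, which matches how compliance rules ("≥600 minutes/day") and sleep
attribution ("Friday night") are defined. Nights spanning a DST change are
therefore measured on the clock, not on elapsed physical time.

### Ingestion rules

* Timestamps parse as ISO-8601 or the `M/D/YYYY H:MM:SS AM/PM` dialect of
  common research exports. An unparseable row is collected as a
  record-level issue with file and line, and the run continues; a CSV whose
  header matches no known stream is a hard error naming the file.
* Duplicate rows for one (participant, minute) within one stream — and
  sub-minute heart-rate samples — are aggregated before grid construction:
  numeric values are averaged (half-up rounding for integer fields) and
  categorical values take the maximal label. The max rather than
  "last-seen" makes the result invariant to row order, which is asserted
  as a property test.
* The dense per-participant grid spans the first to the last observed
  minute; unobserved minutes exist with all fields absent.

## Wear validation

Wear time is defined by heart-rate presence: a minute counts as worn iff a
heart rate in [20, 250] bpm was recorded. Values outside that range are
treated as nonwear because the presence proxy presumes a physiologic
reading. Days are midnight-to-midnight calendar days; first/last partial
days are judged by the same ≥600 / ≥1200 minute thresholds with no special
trimming, since the threshold is a plain presence count. A participant is
valid with at least 5 valid days; when more than 9 days qualify, the
earliest 9 are retained so the analysis window stays a ~1-week protocol.
Retention (rather than exclusion) of >9-day participants is a declared
choice; the alternative would discard the most compliant wearers.

## Sleep segmentation

A sleep cycle is a maximal run of stage-labeled minutes; unlabeled minutes
split cycles. Each candidate night is keyed by the calendar date on which
its 18:00 window opens, making weekday/weekend attribution unambiguous (a
cycle starting 01:00 Saturday belongs to Friday's night key).

* **Rule A** — all cycles with onset in [18:00, 06:00) merge into one main
  period from the first onset to the last wake, with no gap limit. Gap
  minutes surface in WASO, so a pathological merge is visible rather than
  silently discarded. The window is half-open: an onset at exactly 06:00 is
  not in the night window.
* **Rule B** — when Rule A finds nothing, the longest cycle with onset in
  [06:00, 18:00) of the following day seeds the period and is extended by
  subsequent cycles starting within `late_merge_gap_min` (default 60) of
  the running end. This automates what would otherwise be a manual judgment
  for late-onset sleepers; the threshold is configuration, not biology.
  Chaining additionally stops at 18:00 of the following day so no cycle can
  be claimed by two nights.
* Cycles starting after the main period's wake are naps: excluded from
  sleep metrics, but still excluded from "awake sedentary" time.
* A night with no qualifying cycles yields no period and is simply absent
  from per-night tables.

## Sleep metrics

With span = wake − onset in minutes: WASO is the count of stage-3 plus
unlabeled gap minutes inside the span, divided by 60; efficiency is asleep
minutes over span; the midpoint is the arithmetic middle of onset and wake.
Restless (stage-2) minutes count as asleep by default because the coding
distinguishes restlessness from wakefulness; since that reading is
contestable, `restless_as_awake=True` flips them into WASO everywhere.
"Sleep duration" always means the onset-to-wake span, not asleep time —
otherwise efficiency could not be below 1 by construction.

Clock times are averaged on a noon-anchored linear axis (minutes since the
preceding 12:00). Every onset/wake the segmentation can produce lies in
(12:00, 12:00+36 h) relative to that anchor, so the axis never wraps and
ordinary means and SDs are valid; no circular statistics are needed. A
participant whose mean onset falls at or after minute 720 (midnight) is in
the after-midnight onset group. Social jet lag is the absolute difference
between mean weekend (Friday/Saturday night-key) and mean weekday midpoint,
reported in hours; it is absent — not zero — for participants with no
weekend (or no weekday) night among retained nights.

Nights enter participant summaries only when their night key is a retained
valid wear day, and 5–9 nights are required (earliest 9 kept), mirroring
the wear rule.

## Activity metrics

Total steps per day is unconditioned; steps/hour divides steps on worn
minutes by wear hours, since the two metric names read differently.
Intensity minutes are plain label counts; unlabeled minutes contribute to
no bucket (no imputation). Awake sedentary time excludes stage-labeled
minutes and main-period intervals (which also cover in-period gaps); a
period crossing midnight contributes to both days' exclusions.

## Cohort tables

Participant summaries are aggregated with equal weight per participant
regardless of their day counts, using sample (n−1) SDs. Strata are overall,
sex (when metadata is joined), and onset group. The clock matrix reports,
per 15-minute clock bin, the expected number of participants asleep: each
participant contributes the fraction of their retained nights in which any
minute of that bin was spent asleep (stages 1–2) inside the main period.
An empty stratum emits a row with n = 0 and absent statistics.

## Synthetic cohort generator

The generator emulates the behavioral structure of an adolescent wearable
cohort with ~8 days of continuous wear. Defaults were chosen once to land
near published cohort descriptives for this population (about 8883
steps/day, 7.9 h sleep, 93% efficiency, ~0.6 h WASO, onset ~00:16,
~1323 min/day wear) and are configuration, not constants:

* **Wear**: Poisson(3)/day nonwear gaps with LogNormal(μ=3.7, σ=0.7) minute
  lengths (median ~40 min), applied to awake minutes only; whole days go
  missing with probability 0.02.
* **Sleep**: onset 00:16 with 80 min between-participant and 30 min nightly
  SD; span 7.9 h (0.7 h between / 0.6 h within); weekends (Friday/Saturday
  nights) shift onset +45 min and span +30 min; Poisson(6) restless minutes
  and Poisson(5) awake bouts per night with geometric (mean 6 min, cap 45)
  lengths, 30% of bouts rendered as unlabeled gaps that split the night
  into cycles; 10% nap probability (Normal(40, 10) min, morning/afternoon
  only); 5% of participants are late-onset sleepers (onset ~09:30 ± 45 min).
* **Activity**: per-participant daily budgets of 20/23/235 very/moderate/
  light minutes (SD 18/16/65, floored at 0), placed preferentially in the
  07:00–22:00 window; steps per minute are Poisson with rates 130/80/20 by
  intensity and 0 when sedentary; sleep minutes read sedentary with zero
  steps, as devices report.
* **Heart rate**: AR(1) (coefficient 0.9) around 75 bpm awake / 60 bpm
  asleep.

Each participant's stream is seeded by (cohort seed, participant index), so
cohorts are byte-reproducible and participant subsets are stable when the
cohort grows.

Two generation constraints keep the latent truth recoverable by the
segmentation rules, and correspondingly limit what the generator can
represent: cycle-splitting gaps are placed only before 06:00 (a post-06:00
fragment would be dropped by the night-window rule), and late-onset nights
are generated as a single cycle (the fallback rule keeps only the longest
cycle and its forward chain). Real device data can violate both — a split
across 06:00 or a fragmented late sleep would be partially truncated by
this pipeline exactly as it would by the definitions above — so passing
recovery tests demonstrate correctness of the implementation under the
stated rules, not robustness to every fragmentation pattern a device can
emit. Naps are constrained to start after 06:00 and end by ~17:40 so they
can never be captured by a night window. The generator also makes no claim
to physiological realism beyond what the pipeline measures: no heart-rate
variability structure, no intraday circadian harmonics, no correlation
between activity and subsequent sleep.

## Numerical and degenerate-input choices

* Half-up rounding for integer aggregation; onset clock times are floored
  to the minute.
* Empty record lists, mixed-participant inputs, zero-wear retained days and
  <5-day summaries raise; a participant with <5 nights is skipped and
  logged, not an error.
* Sample SDs are undefined (NaN) for n = 1 strata; empty strata report
  n = 0.
* Infeasible generator configurations (probabilities outside [0, 1],
  negative SDs, span ≥ 24 h, onset mean outside its window) fail validation
  before any generation.

## Problem sizes used in validation

The test suite exercises the segmentation oracle on 36,067 exhaustively
enumerated block-coded stage sequences (all 2^14 labeled/absent masks over
5-minute blocks straddling the 06:00 boundary, plus all 3^9
{absent, asleep, awake} sequences around midnight), metric conservation on
1,000 random nights, and parameter recovery on a seeded 200-participant ×
8-day cohort (~2.3 M minutes), with smaller cohorts for idempotence and
round-trip checks. These sizes were chosen to cover the rule boundaries
exhaustively where enumeration is feasible and to make Monte Carlo checks
statistically decisive (3-standard-error bands at n = 200) while keeping
the suite fast.
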