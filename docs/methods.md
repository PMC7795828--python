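# Methods

## Model and assumptions

A *social event* is one timestamped social activity (by default a
conversation). The miner models sociability as a time-of-day histogram:
only the start time of each event is used, binned into `S = 24/t` equal
slots after conversion to a configured timezone (default UTC), because a
slot must mean the same wall-clock period of the day. Durations are
parsed, carried through I/O and ignored by the miner. Events crossing
midnight keep the slot and calendar date of their start.

Events are fanned out to one counting partition per *context attribute*
(CA). Two temporal scales ship by default — day-of-week
(MONDAY…SUNDAY) and weekpart (WEEKDAY/WEEKEND) — and each date maps to
exactly one label per scale; explicit CAs on JSON-lines records (e.g.
weather labels from an external source) are merged in unchanged. Each
partition keeps only the slot-count array and its total `|n|`, so memory
is `O(S)` per context regardless of stream length.

Pattern extraction composes three steps on the summary: the candidate
threshold `S_th = |n|·θ/S` (θ times the uniform per-slot expectation),
element-wise filtering that zeroes sub-threshold slots, and grouping of
maximal adjacent candidate runs, retaining a run when its summed count
is at least `φ·|n|`. Both comparisons are inclusive: a count (or run
sum) exactly at the threshold survives, matching a unit step that is 1
at zero. Runs become clock-time intervals `[first·t, (last+1)·t)`.
Slots 47 and 0 are not adjacent by default; `wrap_midnight=True` merges
edge runs for users whose routines straddle midnight, reporting the
wrapped run as its two clock segments.

Change detection is unsupervised (event streams carry no ground-truth
labels): the Jaccard coefficient on slot sets compares the reference
pattern against weekly observations (abnormal behavior) and against each
newly extracted pattern (routine change, which also replaces the
reference). The reference persists until a significantly different
pattern appears, so slow drifts are eventually caught. Conventions:
`J(∅, ∅) = 1` — identical absent behavior is not a change — and
`J(∅, X) = 0`; the crisp rule fires strictly below the threshold, so
equality does not fire. The first pattern of each context becomes its
reference silently.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `t` | slot length, hours | 0.5 | 30-minute slices (48 slots) resolve typical routines without fragmenting them |
| `θ` | candidate sensitivity (× uniform expectation) | 1.0 | a slot must beat a flat day to be a candidate |
| `φ` | minimum fraction of `|n|` per retained run | 0.3 | keeps only intervals that capture a substantial share of activity |
| `window_days` | observation window | 7 | one calendar week; a day-of-week CA then has one occurrence per window |
| `k` | observations per pattern | 2 | one observation extracts clearly weaker patterns (the evaluation shows it); three or four add little while tripling latency |
| threshold | crisp change threshold | 0.461 | cohort-derived `μ + σ` of routine stability (0.354 + 0.107) |
| timezone | local clock for slotting | UTC | explicit rather than host-dependent; override per deployment |

σ in `μ + σ` is the sample standard deviation (ddof = 1), the
conventional cohort estimate.

Observation windows are consecutive `window_days` blocks anchored at the
stream's first date (calendar weeks, not sliding windows); partitions
reset their counters after each extraction, so `|n|` always refers to
the `k` windows behind the current pattern. Per-CA "consecutive days" in
the stability protocol means consecutive occurrences of that CA (Monday
to next Monday), and a date carrying the CA with zero events contributes
an empty slot set — absence of sociability is behavior, and skipping
such days would bias stability upward.

## Fuzzy drift assessment

The Mamdani system has inputs *sensitivity* and *similarity* and output
*drift*, each on 0–100 with three terms. Inference is standard: singleton
fuzzification, min for AND, implication by clipping, aggregation by max,
and center-of-gravity defuzzification on a uniform grid (default step
0.1; halving the step moves the result by less than the coarser step).
The notification carries the defuzzified value plus the membership
degree of that value in every output term; the monitor's verdict is the
term with the highest degree, ties resolved toward the more severe term.

The default configuration uses low = trapezoid(0, 0, 25, 50),
moderate = triangle(25, 50, 75), high = trapezoid(50, 75, 100, 100) for
all three variables, and a nine-rule severity table (high sensitivity
with low similarity → change, low sensitivity with high similarity →
no change, graded between). The term supports are chosen so adjacent
terms co-fire everywhere in the range: with narrower shoulders (e.g.
low ending at 40 and high starting at 60) only the moderate term fires
for mid-range similarities, the centroid plateaus there, and no
sensitivity can place the change-verdict boundary in that band.
`calibrate_sensitivity` finds, by bisection, the sensitivity whose
change-verdict boundary sits at a crisp threshold; because the boundary
can jump over the exact target, it returns the sensitivity with the
smallest boundary at or above it, erring toward alerting. Custom
configurations load from a YAML/JSON schema (variables with
triangle/trapezoid/point-list terms, rules as term pairs, COG
resolution); only COG defuzzification and singleton inputs are
supported.

## Synthetic data

A `PersonaProfile` plants, per context, preferred clock-time intervals.
Each day, every interval of that day's contexts is expressed with
probability `p_active`; an expressed interval is shifted by a uniform
jitter (±`jitter_minutes`) and receives a Poisson number of events
(mean `events_per_interval_rate`) at uniform times inside it. A Poisson
number of background events (mean `noise_rate`) lands uniformly over the
day, and durations are log-uniform on 1–30 minutes so emitted CSV looks
like real conversation logs. Defaults (rate 4/interval/day,
`p_active` 0.9, jitter 15 min, noise 1/day) describe a fairly regular
student-like routine: most habitual windows realized most days with
occasional out-of-routine conversations.

Routine changes are injected by switching personas on a chosen day over
a continuous date range. Cohorts spread users over `p_active` 0.3–1.0,
jitter 45–0 min and noise 3–0.5 events/day so realized stabilities span
a wide gradient; per-user generators are spawned from the master seed
via `numpy.random.SeedSequence(seed).spawn`, making every stream a pure
function of its specification.

What the generator does *not* emulate: sensor-level artifacts (missed or
merged conversations), multi-week periodicity beyond the two calendar
scales, duration structure correlated with time of day, and correlated
users. Passing tests on this data therefore show the pipeline's
correctness and its qualitative behavior under controlled stability, not
performance figures transferable to any particular real deployment.

## Numerical and design choices

- Counts are int64; thresholds are floats; comparisons are exact
  (inclusive at the boundary), so streaming and batch recomputation
  agree bit-for-bit.
- The monitor closes a context's windows lazily as later events arrive
  and flushes at end-of-stream; notifications are sorted by (date,
  context, kind), making replays byte-identical.
- Malformed input lines are skipped and counted (or raise, in strict
  mode); an empty pattern is a valid value, not an error, and an
  all-zero fuzzy aggregate raises a no-verdict error that the detector
  treats as "no assessment".
- Evaluation problem sizes: the cohort protocols run 24 users for 66
  days with weekly windows and day-of-week contexts — large enough for
  stable Pearson estimates (the association is +0.9-ish across seeds)
  while keeping the full evaluation in a few seconds.
- The MQTT-style root topic is carried in notification payloads, but the
  only sink implemented is JSON-lines; broker publication was left out
  deliberately to keep the monitoring path free of network dependencies.

## Limitations

- θ and φ are set manually; no automatic tuning.
- Patterns model start times only; intensity (event counts, durations)
  is reported as support but not compared by the change detector.
- A routine change is a change in *when* sociability happens; total
  sociability may be conserved. Interpretation is left to the
  specialist.
- With very sparse contexts (e.g. a CA seen once a week), `k` windows of
  accumulation may contain few events, and patterns can be empty; the
  empty-set Jaccard conventions then govern the comparisons.
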