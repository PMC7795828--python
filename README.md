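# sociability

Context-aware sociability-pattern mining and social-behavior change
detection from timestamped social-event streams.

## The problem

Digital-phenotyping studies infer social activity — most commonly
conversations detected by a smartphone — as streams of timestamped
events. Mental-health professionals monitoring such streams want two
things: a compact model of *when* an individual habitually socializes
under each contextual condition (Mondays, weekends, …), and timely
alerts when the observed behavior departs from that model, either as a
one-off **abnormal social behavior** or as a persistent **social routine
change**. This package implements that pipeline as a tested Python
library with a thin CLI, plus a synthetic event generator so every part
is exercisable without external data.

## The method

**Pattern mining.** The day is divided into `S = 24/t` slots of `t`
hours (default `t = 0.5`, 48 slots). For each context attribute (CA) the
miner keeps only a slot-count array and the event total `|n|`. A slot is
a *candidate* when its count reaches

&nbsp;&nbsp;&nbsp;&nbsp;`S_th = |n| · θ / S`,

i.e. `θ` times the uniform per-slot expectation (Eq. 2 zeroes
non-candidates). Maximal runs of adjacent candidate slots are kept as
pattern intervals when their summed count reaches `φ · |n|`. The result
is the **sociability pattern**: the set of `[T_start, T_end)` intervals
in which the individual habitually socializes in that context.

**Change detection.** Behavior is compared with the Jaccard coefficient
`J(A, B) = |A ∩ B| / |A ∪ B|` on slot sets. Each weekly *observation*
(slots with ≥ 1 event) is scored against the current reference pattern;
`J` below the specialist threshold fires an abnormal-behavior event.
Every `k` observations (default 2) a new pattern is extracted; if it
scores below threshold against the reference, a routine-change event
fires and the reference is replaced. A cohort's threshold can be derived
as `μ + σ` of per-user routine stability (mean consecutive-day Jaccard).

**Fuzzy expert layer.** The hard threshold can be replaced by a Mamdani
fuzzy-inference system — inputs *sensitivity* and *similarity*, output
*drift*, min-AND activation, clipped consequents, max aggregation and
center-of-gravity defuzzification — so near-threshold similarities yield
graded verdicts with per-term membership degrees.

## Worked example

`examples/02_detect_changes.py` streams six weeks of a morning/evening
persona followed by four weeks of a night/lunch persona with disjoint
hours through the monitor (threshold 0.461):

```
2024-02-04  WEEKDAY  similarity=1.000  normal
2024-02-11  WEEKDAY  similarity=1.000  maintained
2024-02-11  WEEKDAY  similarity=1.000  normal
2024-02-18  WEEKDAY  similarity=0.000  abnormal_behavior
2024-02-25  WEEKDAY  similarity=0.000  abnormal_behavior
2024-02-25  WEEKDAY  similarity=0.000  routine_change
2024-03-03  WEEKDAY  similarity=1.000  normal
```

The first post-switch observations overlap the old reference not at all
(`J = 0`, abnormal); the first pattern extracted from the new behavior
replaces the reference (one routine change); subsequent weeks score
`J = 1` against the new reference and read as normal — the monitor has
adapted. The other examples mine patterns from a noisy persona
(`01_mine_patterns.py`), grade near-threshold similarities with the
fuzzy layer (`03_fuzzy_drift.py`), and run the cohort protocols
(`04_cohort_evaluation.py`), where prediction performance of patterns
correlates strongly with routine stability (Pearson r ≈ +0.95 at k = 2)
and one observation extracts clearly weaker patterns than two.

The same functionality is available from the shell:

```bash
sociability synth --users 24 --days 66 --seed 1 --out cohort/
sociability mine cohort/u01.csv
sociability monitor cohort/u01.csv --threshold 0.461 --sink notes.jsonl
sociability eval cohort/ --ks 1,2,3,4
```

## Layout

- `src/sociability/` — `events` (parsing, slotting, context enrichment),
  `mining` (slot counting and pattern extraction), `change` (Jaccard
  detection), `fuzzy` (Mamdani FIS), `synth` (persona/cohort generator),
  `evaluation` (stability, prediction performance, Pearson association),
  `monitor` (streaming pipeline + run config), `cli`.
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details and limitations.
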