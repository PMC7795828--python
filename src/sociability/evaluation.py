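"""Evaluation protocols: routine stability, prediction performance, and
their association across a cohort.

*Routine stability* is the mean Jaccard similarity of the active slot
sets of consecutive occurrences of a context (Monday vs next Monday, and
so on); days carrying the context but with zero events contribute an
empty slot set — absent sociability is behavior, not missing data.

*Prediction performance* measures how well a pattern extracted from k
observations predicts the following ones: extract from k windows, score
the pattern against each of the next k windows' slot sets, re-extract
from those windows, and repeat; the mean of all scores is reported.

Across a cohort, user-mean performance is correlated (Pearson) with
user-mean stability, and the cohort stability mean and standard
deviation yield the specialist change threshold mu + sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .change import jaccard
from .events import DEFAULT_SCALES, ContextScale, SlotGrid, SocialEvent, enrich_event
from .mining import ContextCounterState, MinerParams, extract_pattern

DAY_CAS = ("MONDAY", "TUESDAY", "WEDNESDAY", "THURSDAY", "FRIDAY", "SATURDAY", "SUNDAY")


class UndefinedResultError(ValueError):
    """Not enough data for the quantity to be defined."""


def _ensure_enriched(
    events: Sequence[SocialEvent], grid: SlotGrid, scales: Sequence[ContextScale]
) -> list[SocialEvent]:
    return [
        e if e.slot is not None and e.date is not None else enrich_event(e, grid, scales)
        for e in events
    ]


def _stream_span(
    events: Sequence[SocialEvent], span: tuple[date, date] | None
) -> tuple[date, date]:
    if span is not None:
        return span
    dates = [e.date for e in events if e.date is not None]
    if not dates:
        raise UndefinedResultError("empty stream and no explicit span")
    return min(dates), max(dates)


def daily_slotsets(
    events: Sequence[SocialEvent],
    ca: str,
    grid: SlotGrid,
    scales: Sequence[ContextScale] = DEFAULT_SCALES,
    span: tuple[date, date] | None = None,
) -> list[tuple[date, frozenset[int]]]:
    """Active slot set for every date in the span carrying the CA.

    Dates with no events yield an empty set.
    """
    events = _ensure_enriched(events, grid, scales)
    first, last = _stream_span(events, span)
    by_date: dict[date, set[int]] = {}
    for e in events:
        if ca in e.context_attributes:
            by_date.setdefault(e.date, set()).add(e.slot)
    out = []
    d = first
    while d <= last:
        labels = {scale(d) for scale in scales}
        if ca in labels:
            out.append((d, frozenset(by_date.get(d, set()))))
        d += timedelta(days=1)
    return out


def routine_stability(
    events: Sequence[SocialEvent],
    ca: str,
    grid: SlotGrid,
    scales: Sequence[ContextScale] = DEFAULT_SCALES,
    span: tuple[date, date] | None = None,
) -> float:
    """Mean Jaccard between consecutive occurrences of the CA."""
    days = daily_slotsets(events, ca, grid, scales, span)
    if len(days) < 2:
        raise UndefinedResultError(
            f"need >= 2 occurrences of {ca!r}, found {len(days)}"
        )
    sims = [jaccard(a, b) for (_, a), (_, b) in zip(days, days[1:])]
    return float(np.mean(sims))


def window_summaries(
    events: Sequence[SocialEvent],
    ca: str,
    grid: SlotGrid,
    window_days: int = 7,
    scales: Sequence[ContextScale] = DEFAULT_SCALES,
    span: tuple[date, date] | None = None,
) -> list[tuple[tuple[date, date], np.ndarray, frozenset[int]]]:
    """Per-window (window, slot-count array, active slot set) for one CA.

    Windows are consecutive ``window_days``-day blocks anchored at the
    span start; only complete windows are returned.
    """
    events = _ensure_enriched(events, grid, scales)
    first, last = _stream_span(events, span)
    n_windows = ((last - first).days + 1) // window_days
    summaries = []
    for w in range(n_windows):
        w_start = first + timedelta(days=w * window_days)
        w_end = w_start + timedelta(days=window_days - 1)
        counts = np.zeros(grid.num_slots, dtype=np.int64)
        for e in events:
            if ca in e.context_attributes and w_start <= e.date <= w_end:
                counts[e.slot] += 1
        active = frozenset(np.flatnonzero(counts).tolist())
        summaries.append(((w_start, w_end), counts, active))
    return summaries


def _pattern_from_windows(
    windows, ca: str, params: MinerParams
):
    state = ContextCounterState.empty(ca, params.grid)
    for (_, counts, _) in windows:
        state.counts += counts
        state.total += int(counts.sum())
    return extract_pattern(state, params, extracted_at=windows[-1][0][1])


def prediction_performance(
    events: Sequence[SocialEvent],
    ca: str,
    k: int,
    params: MinerParams,
    scales: Sequence[ContextScale] = DEFAULT_SCALES,
    span: tuple[date, date] | None = None,
) -> float:
    """Rolling extract-then-predict score for patterns built from k windows.

    A pattern extracted from windows [i, i+k) is scored against each of
    the windows [i+k, i+2k) that exist; those windows then seed the next
    pattern.  Returns the mean of all scores.
    """
    windows = window_summaries(events, ca, params.grid, params.window_days, scales, span)
    if len(windows) < k + 1:
        raise UndefinedResultError(
            f"need >= {k + 1} complete windows for k={k}, have {len(windows)}"
        )
    scores: list[float] = []
    i = 0
    while i + k < len(windows):
        pattern = _pattern_from_windows(windows[i : i + k], ca, params)
        for j in range(i + k, min(i + 2 * k, len(windows))):
            scores.append(jaccard(pattern.slot_set, windows[j][2]))
        i += k
    return float(np.mean(scores))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; undefined for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise UndefinedResultError("need two equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedResultError("zero variance in at least one input")
    return float(stats.pearsonr(x, y).statistic)


def change_threshold(stabilities: Sequence[float]) -> tuple[float, float, float]:
    """(mu, sigma, mu + sigma) of per-user stability means.

    sigma is the sample standard deviation (ddof=1), the conventional
    cohort estimate; with it the cohort's own variability sets how far
    below typical stability an observation must fall to count as change.
    """
    arr = np.asarray(stabilities, dtype=float)
    if arr.size < 2:
        raise UndefinedResultError("need >= 2 users to set a cohort threshold")
    mu = float(arr.mean())
    sigma = float(arr.std(ddof=1))
    return mu, sigma, mu + sigma


def filter_users_by_coverage(
    streams: Mapping[str, Sequence[SocialEvent]],
    n_days: int,
    min_fraction: float = 0.8,
    grid: SlotGrid | None = None,
    scales: Sequence[ContextScale] = DEFAULT_SCALES,
) -> dict[str, Sequence[SocialEvent]]:
    """Keep users observed on >= ceil(min_fraction * n_days) distinct days."""
    import math

    grid = grid or SlotGrid(0.5)
    need = math.ceil(min_fraction * n_days)
    kept = {}
    for user, events in streams.items():
        enriched = _ensure_enriched(list(events), grid, scales)
        if len({e.date for e in enriched}) >= need:
            kept[user] = events
    return kept


def change_detection_drill(
    profile_a,
    profile_b,
    context: str = "WEEKDAY",
    n_days: int = 70,
    change_day: int = 43,
    start_date: date = date(2024, 1, 1),
    seed: int = 0,
    threshold: float = 0.461,
    params: MinerParams | None = None,
):
    """Persona-switch experiment: stream persona A, then persona B.

    Emulates concatenating two users with different routines: the monitor
    should flag the first post-switch observations as abnormal, recognize
    exactly one routine change at the first pattern extracted from
    persona B's data, and then return to normal.  ``change_day`` defaults
    to the start of an extraction cycle (weekly windows, two observations
    per pattern) so the switch is clean, as when two users' files are
    concatenated.  Returns the notifications for ``context`` in order.
    """
    from .monitor import RunConfig, run_monitor
    from .synth import inject_routine_change

    params = params or MinerParams()
    events = inject_routine_change(
        profile_a, profile_b, change_day=change_day, n_days=n_days,
        start_date=start_date, seed=seed,
    )
    config = RunConfig(
        slot_length_hours=params.grid.slot_length_hours,
        theta=params.theta,
        phi=params.phi,
        window_days=params.window_days,
        observations_per_pattern=params.observations_per_pattern,
        threshold=threshold,
    )
    result = run_monitor(config, events)
    return [n for n in result.notifications if n.context == context]


@dataclass
class EvaluationReport:
    """Cohort evaluation: stability, performance by k, and their association."""

    stability: dict[str, dict[str, float]]            # user -> ca -> mean Jaccard
    performance: dict[int, dict[str, dict[str, float]]]  # k -> user -> ca -> mean
    user_mean_stability: dict[str, float]
    user_mean_performance: dict[int, dict[str, float]]
    overall_r: dict[int, float]                       # k -> Pearson r
    per_ca_r: dict[str, float]                        # ca -> Pearson r at reference k
    reference_k: int
    mu: float
    sigma: float
    threshold: float

    def to_json_dict(self) -> dict:
        return {
            "stability": self.stability,
            "performance": {str(k): v for k, v in self.performance.items()},
            "user_mean_stability": self.user_mean_stability,
            "user_mean_performance": {
                str(k): v for k, v in self.user_mean_performance.items()
            },
            "overall_pearson_r": {str(k): v for k, v in self.overall_r.items()},
            "per_ca_pearson_r": self.per_ca_r,
            "reference_k": self.reference_k,
            "stability_mu": self.mu,
            "stability_sigma": self.sigma,
            "change_threshold": self.threshold,
        }


def evaluate_cohort(
    streams: Mapping[str, Sequence[SocialEvent]],
    params: MinerParams,
    cas: Sequence[str] = DAY_CAS,
    ks: Sequence[int] = (1, 2, 3, 4),
    reference_k: int = 2,
    scales: Sequence[ContextScale] = DEFAULT_SCALES,
    span: tuple[date, date] | None = None,
) -> EvaluationReport:
    """Run stability and prediction-performance protocols over a cohort.

    Per-user, per-CA quantities that are undefined (too little data) are
    skipped; user means average the defined CAs.
    """
    stability: dict[str, dict[str, float]] = {}
    performance: dict[int, dict[str, dict[str, float]]] = {k: {} for k in ks}
    for user, events in streams.items():
        events = list(events)
        stab_ca: dict[str, float] = {}
        for ca in cas:
            try:
                stab_ca[ca] = routine_stability(events, ca, params.grid, scales, span)
            except UndefinedResultError:
                continue
        if stab_ca:
            stability[user] = stab_ca
        for k in ks:
            perf_ca: dict[str, float] = {}
            for ca in cas:
                try:
                    perf_ca[ca] = prediction_performance(events, ca, k, params, scales, span)
                except UndefinedResultError:
                    continue
            if perf_ca:
                performance[k][user] = perf_ca

    user_mean_stability = {
        u: float(np.mean(list(d.values()))) for u, d in stability.items()
    }
    user_mean_performance = {
        k: {u: float(np.mean(list(d.values()))) for u, d in performance[k].items()}
        for k in ks
    }

    overall_r: dict[int, float] = {}
    for k in ks:
        users = sorted(set(user_mean_stability) & set(user_mean_performance[k]))
        try:
            overall_r[k] = pearson_r(
                [user_mean_stability[u] for u in users],
                [user_mean_performance[k][u] for u in users],
            )
        except UndefinedResultError:
            continue

    per_ca_r: dict[str, float] = {}
    for ca in cas:
        users = sorted(
            u for u in stability
            if ca in stability[u]
            and u in performance[reference_k]
            and ca in performance[reference_k][u]
        )
        try:
            per_ca_r[ca] = pearson_r(
                [stability[u][ca] for u in users],
                [performance[reference_k][u][ca] for u in users],
            )
        except UndefinedResultError:
            continue

    mu, sigma, threshold = change_threshold(list(user_mean_stability.values()))
    return EvaluationReport(
        stability=stability,
        performance=performance,
        user_mean_stability=user_mean_stability,
        user_mean_performance=user_mean_performance,
        overall_r=overall_r,
        per_ca_r=per_ca_r,
        reference_k=reference_k,
        mu=mu,
        sigma=sigma,
        threshold=threshold,
    )
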