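"""Incremental sociability-pattern mining over per-context slot counts.

The miner keeps, for every context attribute, only a summary of the event
stream: an array of S per-slot counters plus the running total |n|.
Pattern extraction is a three-step pipeline on that summary:

1. candidate threshold  Sth = |n| * theta / S   — theta times the uniform
   per-slot expectation;
2. candidate filtering  Cs[i] = counts[i] if counts[i] >= Sth else 0;
3. adjacency grouping   maximal runs of non-zero candidate slots are kept
   as pattern intervals when their summed count >= phi * |n|.

Both boundaries are inclusive (a unit step defined as 1 at zero).  The
result is a :class:`SociabilityPattern`: the set of time-of-day intervals
in which the monitored individual habitually socializes in that context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

import numpy as np

from .events import SlotGrid, SocialEvent


@dataclass(frozen=True)
class MinerParams:
    """Tunable parameters of the pattern miner.

    theta scales the candidate-slot threshold relative to the uniform
    expectation |n|/S; phi is the fraction of all events an interval must
    capture to count as a pattern; window_days is the length of one
    observation window; observations_per_pattern (k) is how many windows
    are accumulated before each extraction.  wrap_midnight allows runs to
    join across the 23:59->00:00 boundary (off by default: patterns are
    presented as within-day intervals).
    """

    grid: SlotGrid = SlotGrid(0.5)
    theta: float = 1.0
    phi: float = 0.3
    window_days: int = 7
    observations_per_pattern: int = 2
    wrap_midnight: bool = False

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must be in [0, 1]")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.observations_per_pattern < 1:
            raise ValueError("observations_per_pattern must be >= 1")


@dataclass
class ContextCounterState:
    """Per-context slot-count summary: S counters and the total |n|."""

    context: str
    counts: np.ndarray
    total: int = 0

    @classmethod
    def empty(cls, context: str, grid: SlotGrid) -> "ContextCounterState":
        return cls(context=context, counts=np.zeros(grid.num_slots, dtype=np.int64))

    def copy(self) -> "ContextCounterState":
        return ContextCounterState(self.context, self.counts.copy(), self.total)

    def reset(self) -> None:
        self.counts[:] = 0
        self.total = 0


@dataclass(frozen=True)
class SociabilityPattern:
    """Frequent time-of-day intervals for one context.

    ``intervals`` are [start, end) clock-time pairs in hours since
    midnight, one per maximal retained slot run; ``slot_set`` is the union
    of their slots; ``support`` the event count inside the pattern.
    """

    context: str
    intervals: tuple[tuple[float, float], ...]
    slot_set: frozenset[int]
    support: int
    extracted_at: date | None = None
    n_observations: int = 1

    @property
    def is_empty(self) -> bool:
        return not self.slot_set

    def to_json_dict(self) -> dict:
        def hhmm(hours: float) -> str:
            m = round(hours * 60) % (24 * 60)
            return f"{m // 60:02d}:{m % 60:02d}"

        return {
            "context": self.context,
            "intervals": [
                {"start": hhmm(a), "end": "24:00" if b == 24.0 else hhmm(b)}
                for a, b in self.intervals
            ],
            "slot_set": sorted(self.slot_set),
            "support": self.support,
            "extracted_at": self.extracted_at.isoformat() if self.extracted_at else None,
            "n_observations": self.n_observations,
        }


def update_counts(state: ContextCounterState, event: SocialEvent) -> ContextCounterState:
    """Count one event into its slot; increments exactly one cell and |n|."""
    if event.slot is None:
        raise ValueError("event has no slot; enrich it first")
    if state.context not in event.context_attributes:
        raise ValueError(
            f"event CAs {set(event.context_attributes)} do not include "
            f"partition context {state.context!r}"
        )
    if not 0 <= event.slot < state.counts.shape[0]:
        raise ValueError(f"slot {event.slot} out of range")
    state.counts[event.slot] += 1
    state.total += 1
    return state


def slot_threshold(total: int, theta: float, grid: SlotGrid) -> float:
    """Candidate threshold Sth = |n| * theta / S."""
    if total < 0:
        raise ValueError("total must be >= 0")
    return total * theta / grid.num_slots


def filter_candidate_slots(counts: np.ndarray, sth: float) -> np.ndarray:
    """Zero out slots below the threshold; counts at the threshold survive."""
    counts = np.asarray(counts)
    return np.where(counts >= sth, counts, 0)


def group_patterns(
    candidates: np.ndarray,
    phi: float,
    total: int,
    wrap_midnight: bool = False,
) -> list[tuple[int, int]]:
    """Group adjacent non-zero candidate slots into retained runs.

    Returns runs as (first_slot, last_slot) inclusive pairs in slot order;
    a run is retained iff its summed count >= phi * |n| (equality kept).
    With ``wrap_midnight``, a run touching the last slot joins one touching
    slot 0 and is reported with first_slot > last_slot.
    """
    candidates = np.asarray(candidates)
    runs: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(candidates):
        if v > 0 and start is None:
            start = i
        elif v <= 0 and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(candidates) - 1))

    if (
        wrap_midnight
        and len(runs) >= 2
        and runs[0][0] == 0
        and runs[-1][1] == len(candidates) - 1
    ):
        first, last = runs[0], runs.pop()
        runs[0] = (last[0], first[1])  # wrapped run, first_slot > last_slot

    def run_sum(run: tuple[int, int]) -> float:
        a, b = run
        if a <= b:
            return float(candidates[a : b + 1].sum())
        return float(candidates[a:].sum() + candidates[: b + 1].sum())

    cutoff = phi * total
    return [r for r in runs if run_sum(r) >= cutoff]


def extract_pattern(
    state: ContextCounterState,
    params: MinerParams,
    extracted_at: date | None = None,
) -> SociabilityPattern:
    """Run the full threshold/filter/group pipeline on a count summary."""
    sth = slot_threshold(state.total, params.theta, params.grid)
    cs = filter_candidate_slots(state.counts, sth)
    runs = group_patterns(cs, params.phi, state.total, params.wrap_midnight)

    t = params.grid.slot_length_hours
    s = params.grid.num_slots
    intervals: list[tuple[float, float]] = []
    slots: set[int] = set()
    support = 0
    for a, b in runs:
        if a <= b:
            intervals.append((a * t, (b + 1) * t))
            run_slots = range(a, b + 1)
        else:  # wrapped run: report the two clock segments
            intervals.append((a * t, 24.0))
            intervals.append((0.0, (b + 1) * t))
            run_slots = list(range(a, s)) + list(range(0, b + 1))
        for i in run_slots:
            slots.add(i)
            support += int(cs[i])
    intervals.sort()
    return SociabilityPattern(
        context=state.context,
        intervals=tuple(intervals),
        slot_set=frozenset(slots),
        support=support,
        extracted_at=extracted_at,
        n_observations=params.observations_per_pattern,
    )


class ContextPartitionMiner:
    """Streaming front-end: fans each event out to all its CA partitions.

    Mirrors the enrich -> context-partition -> count-table stages of a
    stream-processing pipeline: one count summary per context attribute,
    updated per event, with extraction on demand.
    """

    def __init__(self, params: MinerParams):
        self.params = params
        self._states: dict[str, ContextCounterState] = {}

    def process(self, event: SocialEvent) -> None:
        for ca in event.context_attributes:
            state = self._states.get(ca)
            if state is None:
                state = ContextCounterState.empty(ca, self.params.grid)
                self._states[ca] = state
            update_counts(state, event)

    def state(self, context: str) -> ContextCounterState:
        return self._states.setdefault(
            context, ContextCounterState.empty(context, self.params.grid)
        )

    @property
    def contexts(self) -> list[str]:
        return sorted(self._states)

    def extract(self, context: str, extracted_at: date | None = None) -> SociabilityPattern:
        return extract_pattern(self.state(context), self.params, extracted_at)

    def reset(self, context: str | None = None) -> None:
        if context is None:
            for state in self._states.values():
                state.reset()
        elif context in self._states:
            self._states[context].reset()
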