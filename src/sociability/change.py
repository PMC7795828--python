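"""Jaccard-based abnormal-behavior and routine-change detection.

Two situations are flagged, both per context attribute:

* **abnormal social behavior** — one observation (the slots active during
  one window) overlaps poorly with the current reference pattern;
* **social routine change** — a *newly extracted pattern* overlaps poorly
  with the reference pattern, in which case the reference is replaced by
  the new routine (slow drifts are caught by keeping the first pattern
  until a significantly different one appears).

Overlap is the Jaccard coefficient on slot sets.  The decision rule is
either crisp (similarity strictly below a specialist threshold) or fuzzy
(the drift FIS verdict is "change").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

from .events import SlotGrid, SocialEvent, slot_index
from .fuzzy import DriftAssessment, FISConfig, NoVerdictError, fis_assess
from .mining import SociabilityPattern

ABNORMAL = "abnormal_behavior"
ROUTINE_CHANGE = "routine_change"
MAINTAINED = "maintained"
NORMAL = "normal"


def jaccard(a: frozenset[int] | set[int], b: frozenset[int] | set[int]) -> float:
    """|a n b| / |a u b| on slot sets; J(empty, empty) is defined as 1.

    Two empty slot sets mean identical (absent) behavior, which must not
    fire change events; empty vs non-empty is 0.
    """
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union


@dataclass(frozen=True)
class Observation:
    """One window's social behavior for a context: its active slot set."""

    context: str
    window: tuple[date, date]
    active_slots: frozenset[int]
    event_count: int

    def __post_init__(self) -> None:
        if self.event_count < len(self.active_slots):
            raise ValueError("event_count cannot be below the active slot count")


def observation_slotset(
    events: list[SocialEvent],
    grid: SlotGrid,
    context: str,
    window: tuple[date, date],
    tz=None,
) -> Observation:
    """Summarize a window's events as the set of slots with >= 1 event."""
    slots = set()
    for event in events:
        slots.add(event.slot if event.slot is not None else slot_index(event.start, grid, tz))
    return Observation(
        context=context,
        window=window,
        active_slots=frozenset(slots),
        event_count=len(events),
    )


@dataclass(frozen=True)
class DetectorPolicy:
    """How the below-threshold decision is made.

    Crisp mode fires when similarity < threshold (strict).  Fuzzy mode
    feeds (sensitivity, similarity*100) to the FIS and fires when the
    output term with the highest membership at the defuzzified value is
    the most severe one ("change").
    """

    mode: str = "crisp"
    threshold: float | None = 0.461
    sensitivity: float | None = None
    fis: FISConfig | None = None

    def __post_init__(self) -> None:
        if self.mode == "crisp":
            if self.threshold is None or not 0.0 <= self.threshold <= 1.0:
                raise ValueError("crisp mode requires a threshold in [0, 1]")
        elif self.mode == "fuzzy":
            if self.fis is None or self.sensitivity is None:
                raise ValueError("fuzzy mode requires a FIS config and a sensitivity")
        else:
            raise ValueError(f"unknown detector mode {self.mode!r}")

    def decide(self, similarity: float) -> tuple[bool, DriftAssessment | None]:
        """(fires, optional drift assessment) for one similarity value."""
        if self.mode == "crisp":
            return similarity < self.threshold, None
        try:
            assessment = fis_assess(self.fis, self.sensitivity, similarity * 100.0)
        except NoVerdictError:
            return False, None
        change_term = self.fis.output.term_order[-1]
        return assessment.verdict == change_term, assessment


@dataclass(frozen=True)
class ChangeNotification:
    """Emitted record: what fired, when, for which context, and how close."""

    kind: str
    date: date | None
    context: str
    similarity: float
    drift: DriftAssessment | None = None

    def to_json_dict(self, root_topic: str | None = None) -> dict:
        obj = {
            "kind": self.kind,
            "date": self.date.isoformat() if self.date else None,
            "context": self.context,
            "similarity": round(self.similarity, 6),
        }
        if self.drift is not None:
            obj["drift"] = self.drift.to_json_dict()
        if root_topic is not None:
            obj["topic"] = f"{root_topic}/{self.context}"
        return obj


def assess_observation(
    reference: SociabilityPattern,
    obs: Observation,
    policy: DetectorPolicy,
) -> ChangeNotification:
    """Compare one observation against the reference pattern."""
    if reference.context != obs.context:
        raise ValueError(
            f"context mismatch: pattern {reference.context!r} vs observation {obs.context!r}"
        )
    similarity = jaccard(reference.slot_set, obs.active_slots)
    fires, drift = policy.decide(similarity)
    return ChangeNotification(
        kind=ABNORMAL if fires else NORMAL,
        date=obs.window[1],
        context=obs.context,
        similarity=similarity,
        drift=drift,
    )


def assess_pattern_update(
    reference: SociabilityPattern,
    new_pattern: SociabilityPattern,
    policy: DetectorPolicy,
) -> tuple[SociabilityPattern, ChangeNotification]:
    """Compare a newly extracted pattern against the reference.

    Returns (reference', notification): on a routine change the reference
    is replaced by the new pattern, otherwise it is maintained unchanged.
    """
    if reference.context != new_pattern.context:
        raise ValueError("context mismatch between reference and new pattern")
    similarity = jaccard(reference.slot_set, new_pattern.slot_set)
    fires, drift = policy.decide(similarity)
    notification = ChangeNotification(
        kind=ROUTINE_CHANGE if fires else MAINTAINED,
        date=new_pattern.extracted_at,
        context=new_pattern.context,
        similarity=similarity,
        drift=drift,
    )
    return (new_pattern if fires else reference), notification
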