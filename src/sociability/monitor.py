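"""End-to-end monitoring pipeline and its run configuration.

Replays an event stream in time order through enrichment, per-context
counting, pattern extraction every k observation windows, and
abnormal-behavior / routine-change assessment against a per-context
reference pattern.  The first pattern extracted for a context becomes its
reference silently; afterwards every complete window is assessed as an
observation and every k-th window triggers a pattern extraction that may
replace the reference.  Notifications go to a JSONL sink.  The whole path
is deterministic: replaying the same input with the same configuration
yields byte-identical logs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .change import (
    ABNORMAL,
    MAINTAINED,
    NORMAL,
    ROUTINE_CHANGE,
    ChangeNotification,
    DetectorPolicy,
    Observation,
    assess_observation,
    assess_pattern_update,
)
from .events import (
    DAY_OF_WEEK,
    DEFAULT_SCALES,
    WEEKPART,
    SlotGrid,
    SocialEvent,
    read_events,
)
from .fuzzy import FISConfig, default_fis, load_fis_config
from .mining import ContextCounterState, MinerParams, SociabilityPattern, extract_pattern

logger = logging.getLogger("sociability")

_SCALES_BY_NAME = {"day_of_week": DAY_OF_WEEK, "weekpart": WEEKPART}


class RunConfig(BaseModel):
    """Full run configuration, loadable from YAML or CLI flags.

    Defaults echo a 30-minute grid (48 slots), theta=1, phi=0.3, weekly
    windows, two observations per pattern, and a crisp threshold of 0.461
    — the cohort-derived mu + sigma.
    """

    input: Optional[str] = None
    dialect: str = "studentlife_csv"
    timezone: str = "UTC"
    slot_length_hours: float = 0.5
    theta: float = Field(default=1.0, ge=0.0)
    phi: float = Field(default=0.3, ge=0.0, le=1.0)
    scales: list[str] = ["day_of_week", "weekpart"]
    window_days: int = Field(default=7, ge=1)
    observations_per_pattern: int = Field(default=2, ge=1)
    wrap_midnight: bool = False
    mode: str = "crisp"
    threshold: float = Field(default=0.461, ge=0.0, le=1.0)
    sensitivity: Optional[float] = None
    fis_config: Optional[str] = None
    root_topic: str = "com/lsdi/sociability"
    enable_abnormal: bool = True
    enable_change: bool = True
    jsonl_sink: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.dialect not in ("studentlife_csv", "jsonl"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.mode not in ("crisp", "fuzzy"):
            raise ValueError(f"unknown detector mode {self.mode!r}")
        if self.mode == "fuzzy" and self.sensitivity is None:
            raise ValueError("fuzzy mode requires a sensitivity (0-100)")
        for name in self.scales:
            if name not in _SCALES_BY_NAME:
                raise ValueError(
                    f"unknown scale {name!r}; known: {sorted(_SCALES_BY_NAME)}"
                )
        SlotGrid(self.slot_length_hours)  # validates divisibility
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with Path(path).open() as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def miner_params(self) -> MinerParams:
        return MinerParams(
            grid=SlotGrid(self.slot_length_hours),
            theta=self.theta,
            phi=self.phi,
            window_days=self.window_days,
            observations_per_pattern=self.observations_per_pattern,
            wrap_midnight=self.wrap_midnight,
        )

    def scale_objects(self):
        return tuple(_SCALES_BY_NAME[name] for name in self.scales)

    def detector_policy(self) -> DetectorPolicy:
        if self.mode == "crisp":
            return DetectorPolicy(mode="crisp", threshold=self.threshold)
        fis: FISConfig = (
            load_fis_config(self.fis_config) if self.fis_config else default_fis()
        )
        return DetectorPolicy(mode="fuzzy", sensitivity=self.sensitivity, fis=fis)


@dataclass
class MonitorResult:
    """What a monitoring run produced, plus bookkeeping counts."""

    notifications: list[ChangeNotification]
    patterns: dict[str, SociabilityPattern]   # final reference per context
    events_read: int
    events_skipped: int
    patterns_extracted: int

    def summary(self) -> dict:
        kinds = {}
        for n in self.notifications:
            kinds[n.kind] = kinds.get(n.kind, 0) + 1
        return {
            "events_read": self.events_read,
            "events_skipped": self.events_skipped,
            "patterns_extracted": self.patterns_extracted,
            "notifications": kinds,
            "contexts": sorted(self.patterns),
        }


@dataclass
class _ContextTracker:
    """Per-context streaming state across observation windows."""

    state: ContextCounterState
    reference: SociabilityPattern | None = None
    windows_since_extraction: int = 0
    window_slots: set[int] = field(default_factory=set)
    window_events: int = 0


def run_monitor(
    config: RunConfig, events: Sequence[SocialEvent] | None = None
) -> MonitorResult:
    """Replay a stream through the full mining + detection pipeline.

    Events may be passed directly (already parsed) or read from
    ``config.input``.  Only contexts that actually occur are tracked; a
    context's clock advances in windows of ``window_days`` calendar days
    anchored at the stream's first date.
    """
    grid = SlotGrid(config.slot_length_hours)
    scales = config.scale_objects()
    params = config.miner_params()
    policy = config.detector_policy()
    k = config.observations_per_pattern

    skipped = 0
    if events is None:
        if config.input is None:
            raise ValueError("no input path configured and no events passed")
        raw = list(
            read_events(
                config.input, config.dialect, config.timezone, grid, scales,
                skip_errors=True,
            )
        )
        with Path(config.input).open() as fh:
            n_lines = sum(
                1 for line in fh
                if line.strip() and not line.startswith("start_timestamp")
            )
        skipped = n_lines - len(raw)
        if skipped:
            logger.warning("skipped %d malformed record(s)", skipped)
        events = raw
    else:
        from .events import enrich_event

        events = [
            e if e.slot is not None and e.date is not None
            else enrich_event(e, grid, scales, config.timezone)
            for e in events
        ]
    events = sorted(events, key=lambda e: e.start)

    notifications: list[ChangeNotification] = []
    trackers: dict[str, _ContextTracker] = {}
    patterns_extracted = 0

    if not events:
        return MonitorResult([], {}, 0, skipped, 0)

    first_date = events[0].date
    window_of = lambda d: (d - first_date).days // config.window_days

    def close_window(ca: str, tracker: _ContextTracker, window_idx: int) -> None:
        nonlocal patterns_extracted
        w_end = first_date + timedelta(days=(window_idx + 1) * config.window_days - 1)
        if tracker.reference is not None and config.enable_abnormal:
            obs = Observation(
                context=ca,
                window=(w_end - timedelta(days=config.window_days - 1), w_end),
                active_slots=frozenset(tracker.window_slots),
                event_count=tracker.window_events,
            )
            notifications.append(assess_observation(tracker.reference, obs, policy))
        tracker.window_slots = set()
        tracker.window_events = 0
        tracker.windows_since_extraction += 1
        if tracker.windows_since_extraction >= k:
            new_pattern = extract_pattern(tracker.state, params, extracted_at=w_end)
            patterns_extracted += 1
            if tracker.reference is None:
                tracker.reference = new_pattern  # first pattern: silent reference
            elif config.enable_change:
                tracker.reference, note = assess_pattern_update(
                    tracker.reference, new_pattern, policy
                )
                notifications.append(note)
            tracker.state.reset()
            tracker.windows_since_extraction = 0

    current_window: dict[str, int] = {}
    for event in events:
        w = window_of(event.date)
        for ca in sorted(event.context_attributes):
            tracker = trackers.get(ca)
            if tracker is None:
                tracker = _ContextTracker(state=ContextCounterState.empty(ca, grid))
                trackers[ca] = tracker
                current_window[ca] = w
            while current_window[ca] < w:
                close_window(ca, tracker, current_window[ca])
                current_window[ca] += 1
            tracker.state.counts[event.slot] += 1
            tracker.state.total += 1
            tracker.window_slots.add(event.slot)
            tracker.window_events += 1

    last_window = window_of(events[-1].date)
    for ca in sorted(trackers):
        tracker = trackers[ca]
        while current_window[ca] <= last_window:
            close_window(ca, tracker, current_window[ca])
            current_window[ca] += 1

    notifications.sort(key=lambda n: (n.date or first_date, n.context, n.kind))

    if config.jsonl_sink:
        with Path(config.jsonl_sink).open("w") as fh:
            for note in notifications:
                fh.write(json.dumps(note.to_json_dict(config.root_topic)) + "\n")

    final_patterns = {
        ca: t.reference for ca, t in trackers.items() if t.reference is not None
    }
    result = MonitorResult(
        notifications=notifications,
        patterns=final_patterns,
        events_read=len(events),
        events_skipped=skipped,
        patterns_extracted=patterns_extracted,
    )
    logger.info("monitor summary: %s", result.summary())
    return result
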