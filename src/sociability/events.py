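"""Social-event parsing, time-slot assignment and context enrichment.

A social event is one timestamped social activity (typically a detected
conversation).  Events are binned by *start time* into equal-length
time-of-day slots, and tagged with context attributes (CAs) derived from
the calendar date on one or more temporal scales (day-of-week,
weekday/weekend).  Two input dialects are supported:

* ``studentlife_csv`` — conversation logs with header
  ``start_timestamp,end_timestamp`` in Unix seconds, one row per
  conversation;
* ``jsonl`` — one JSON object per line with keys ``type``, ``start``,
  optional ``end`` and optional explicit ``cas``.

Slotting and dating are local-clock operations: timestamps are converted
to a configured timezone (default UTC) before any time-of-day arithmetic,
so a slot always means the same wall-clock period of the day.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence
from zoneinfo import ZoneInfo


class EventParseError(ValueError):
    """A record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EventValidationError(ValueError):
    """A parsed record violates an event invariant (e.g. end < start)."""


def _resolve_tz(tz: str | ZoneInfo | None) -> ZoneInfo | timezone:
    if tz is None:
        return timezone.utc
    if isinstance(tz, str):
        return timezone.utc if tz.upper() == "UTC" else ZoneInfo(tz)
    return tz


@dataclass(frozen=True)
class SlotGrid:
    """Equal-size division of the day into S = 24/t slots of t hours."""

    slot_length_hours: float = 0.5

    def __post_init__(self) -> None:
        t = self.slot_length_hours
        if t <= 0 or t > 24:
            raise ValueError(f"slot length must be in (0, 24] hours, got {t}")
        s = 24.0 / t
        if abs(s - round(s)) > 1e-9:
            raise ValueError(f"slot length {t} h does not divide 24 h evenly")

    @property
    def num_slots(self) -> int:
        return round(24.0 / self.slot_length_hours)

    def slot_of_minutes(self, minutes_since_midnight: float) -> int:
        slot = math.floor(minutes_since_midnight / (60.0 * self.slot_length_hours))
        return min(max(slot, 0), self.num_slots - 1)

    def slot_clock_bounds(self, slot: int) -> tuple[float, float]:
        """Clock-time bounds [start, end) of a slot, in hours since midnight."""
        t = self.slot_length_hours
        return slot * t, (slot + 1) * t


@dataclass(frozen=True)
class ContextScale:
    """Maps a calendar date to exactly one context-attribute label."""

    name: str
    mapper: Callable[[date], str]

    def __call__(self, d: date) -> str:
        return self.mapper(d)


_DAY_NAMES = (
    "MONDAY", "TUESDAY", "WEDNESDAY", "THURSDAY",
    "FRIDAY", "SATURDAY", "SUNDAY",
)

#: Fine-grained temporal scale: MONDAY .. SUNDAY.
DAY_OF_WEEK = ContextScale("day_of_week", lambda d: _DAY_NAMES[d.weekday()])

#: Broad temporal scale: WEEKDAY (Mon-Fri) vs WEEKEND (Sat, Sun).
WEEKPART = ContextScale(
    "weekpart", lambda d: "WEEKEND" if d.weekday() >= 5 else "WEEKDAY"
)

#: The two scales used for conversation streams by default.
DEFAULT_SCALES: tuple[ContextScale, ...] = (DAY_OF_WEEK, WEEKPART)


@dataclass(frozen=True)
class SocialEvent:
    """One timestamped social activity, optionally slot/context enriched."""

    activity_type: str
    start: datetime
    end: datetime | None = None
    slot: int | None = None
    context_attributes: frozenset[str] = frozenset()
    date: date | None = None

    def __post_init__(self) -> None:
        if self.end is not None and self.end < self.start:
            raise EventValidationError(
                f"event end {self.end} precedes start {self.start}"
            )

    @property
    def duration_seconds(self) -> float | None:
        if self.end is None:
            return None
        return (self.end - self.start).total_seconds()


def slot_index(start: datetime, grid: SlotGrid, tz: str | ZoneInfo | None = None) -> int:
    """Slot of a timestamp: floor(minutes since local midnight / (60 t))."""
    tzinfo = _resolve_tz(tz)
    local = start.astimezone(tzinfo) if start.tzinfo else start.replace(tzinfo=tzinfo)
    minutes = local.hour * 60 + local.minute + local.second / 60.0
    return grid.slot_of_minutes(minutes)


def derive_context_attributes(
    d: date, scales: Sequence[ContextScale]
) -> frozenset[str]:
    """Union of each configured scale's label for the date."""
    return frozenset(scale(d) for scale in scales)


def enrich_event(
    event: SocialEvent,
    grid: SlotGrid,
    scales: Sequence[ContextScale] = DEFAULT_SCALES,
    tz: str | ZoneInfo | None = None,
) -> SocialEvent:
    """Attach slot, local calendar date and context attributes.

    Explicit CAs already on the event (jsonl dialect) are merged with the
    scale-derived ones.  Events crossing midnight keep the date and slot
    of their start.
    """
    tzinfo = _resolve_tz(tz)
    local = (
        event.start.astimezone(tzinfo)
        if event.start.tzinfo
        else event.start.replace(tzinfo=tzinfo)
    )
    d = local.date()
    cas = event.context_attributes | derive_context_attributes(d, scales)
    return replace(
        event,
        slot=slot_index(event.start, grid, tzinfo),
        context_attributes=cas,
        date=d,
    )


def _parse_timestamp(value: object, tz: ZoneInfo | timezone) -> datetime:
    if isinstance(value, (int, float)):
        return datetime.fromtimestamp(float(value), tz=timezone.utc).astimezone(tz)
    if isinstance(value, str):
        v = value.strip()
        try:
            return datetime.fromtimestamp(float(v), tz=timezone.utc).astimezone(tz)
        except ValueError:
            pass
        dt = datetime.fromisoformat(v)
        return dt.astimezone(tz) if dt.tzinfo else dt.replace(tzinfo=tz)
    raise ValueError(f"unsupported timestamp value {value!r}")


def parse_event_record(
    record: str,
    dialect: str,
    tz: str | ZoneInfo | None = None,
    line_number: int | None = None,
) -> SocialEvent:
    """Parse one text record into an (un-enriched) :class:`SocialEvent`.

    ``studentlife_csv`` rows are ``start_timestamp,end_timestamp`` in Unix
    seconds and default the activity type to ``"conversation"``; ``jsonl``
    objects carry ``type``, ``start``, optional ``end`` and optional
    explicit ``cas`` labels.
    """
    tzinfo = _resolve_tz(tz)
    record = record.strip()
    if dialect == "studentlife_csv":
        parts = record.split(",")
        if len(parts) != 2:
            raise EventParseError(
                f"expected 'start,end', got {record!r}", line_number
            )
        try:
            start_ts, end_ts = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise EventParseError(str(exc), line_number) from exc
        return SocialEvent(
            activity_type="conversation",
            start=_parse_timestamp(start_ts, tzinfo),
            end=_parse_timestamp(end_ts, tzinfo),
        )
    if dialect == "jsonl":
        try:
            obj = json.loads(record)
        except json.JSONDecodeError as exc:
            raise EventParseError(f"invalid JSON: {exc}", line_number) from exc
        if "start" not in obj:
            raise EventParseError("missing required key 'start'", line_number)
        try:
            start = _parse_timestamp(obj["start"], tzinfo)
            end = _parse_timestamp(obj["end"], tzinfo) if obj.get("end") is not None else None
        except (ValueError, TypeError) as exc:
            raise EventParseError(str(exc), line_number) from exc
        return SocialEvent(
            activity_type=obj.get("type", "conversation"),
            start=start,
            end=end,
            context_attributes=frozenset(obj.get("cas", ())),
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def read_events(
    path: str | Path,
    dialect: str = "studentlife_csv",
    tz: str | ZoneInfo | None = None,
    grid: SlotGrid | None = None,
    scales: Sequence[ContextScale] = DEFAULT_SCALES,
    skip_errors: bool = False,
) -> Iterator[SocialEvent]:
    """Stream events from a file, enriched when a grid is given.

    With ``skip_errors`` malformed lines are skipped (callers can count
    them by comparing yields against line totals); otherwise the first bad
    line raises.
    """
    path = Path(path)
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if dialect == "studentlife_csv" and i == 1 and line.startswith("start_timestamp"):
                continue
            try:
                event = parse_event_record(line, dialect, tz, line_number=i)
            except (EventParseError, EventValidationError):
                if skip_errors:
                    continue
                raise
            if grid is not None:
                event = enrich_event(event, grid, scales, tz)
            yield event


def event_to_json_dict(event: SocialEvent) -> dict:
    obj: dict = {"type": event.activity_type, "start": event.start.isoformat()}
    if event.end is not None:
        obj["end"] = event.end.isoformat()
    if event.context_attributes:
        obj["cas"] = sorted(event.context_attributes)
    return obj


def write_jsonl(events: Iterable[SocialEvent], path: str | Path) -> int:
    """Write events one JSON object per line; returns the number written."""
    n = 0
    with Path(path).open("w") as fh:
        for event in events:
            fh.write(json.dumps(event_to_json_dict(event)) + "\n")
            n += 1
    return n


def write_studentlife_csv(events: Iterable[SocialEvent], path: str | Path) -> int:
    """Write events as StudentLife-style conversation CSV (Unix seconds)."""
    n = 0
    with Path(path).open("w") as fh:
        fh.write("start_timestamp,end_timestamp\n")
        for event in events:
            start = int(event.start.timestamp())
            end = int(event.end.timestamp()) if event.end is not None else start
            fh.write(f"{start},{end}\n")
            n += 1
    return n
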