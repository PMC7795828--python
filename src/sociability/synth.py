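"""Synthetic social-event streams with planted routines.

Each persona has, per context attribute, a set of preferred time-of-day
intervals.  On each day, every interval of that day's contexts is
expressed with probability ``p_active``; when expressed it receives a
Poisson number of conversation events at uniformly jittered times inside
the interval.  Uniform background events model out-of-routine sociability.
Event durations are drawn log-uniform between 1 and 30 minutes (carried
through I/O, unused by the miner).

A routine change is injected by switching personas on a chosen day —
emulating the concatenation of two real users with different habits.
All streams are pure functions of their seed: per-day draws come from a
single generator consumed in day order, and per-user generators are
spawned from the master seed with ``numpy``'s ``SeedSequence(seed).spawn``
(the documented, release-stable splitting rule).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .events import DEFAULT_SCALES, ContextScale, SocialEvent

_DAY_SECONDS = 24 * 3600


@dataclass(frozen=True)
class PersonaProfile:
    """Distributional description of one synthetic user's routine.

    ``intervals`` maps a context label (e.g. WEEKDAY, SATURDAY) to planted
    clock-time intervals in hours since midnight, non-overlapping within a
    context.  ``events_per_interval_rate`` is the Poisson mean of events
    per expressed interval per day; ``p_active`` the probability an
    interval is expressed on a given day (day-to-day stability);
    ``jitter_minutes`` a uniform shift applied to the whole interval each
    day; ``noise_rate`` the Poisson mean of uniform background events per
    day.
    """

    intervals: Mapping[str, tuple[tuple[float, float], ...]]
    events_per_interval_rate: float = 4.0
    p_active: float = 0.9
    jitter_minutes: float = 15.0
    noise_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_active <= 1.0:
            raise ValueError("p_active must be in [0, 1]")
        if min(self.events_per_interval_rate, self.jitter_minutes, self.noise_rate) < 0:
            raise ValueError("rates and jitter must be >= 0")
        for ca, ivs in self.intervals.items():
            ordered = sorted(ivs)
            for (a, b) in ordered:
                if not (0.0 <= a < b <= 24.0):
                    raise ValueError(f"interval ({a}, {b}) outside [0, 24) for {ca!r}")
            for (_, b), (a2, _) in zip(ordered, ordered[1:]):
                if a2 < b:
                    raise ValueError(f"overlapping intervals for context {ca!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort; fixes the streams byte-for-byte."""

    n_users: int
    n_days: int = 66
    start_date: date = date(2024, 1, 1)
    seed: int = 0
    profiles: tuple[PersonaProfile, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_users < 1 or self.n_days < 1:
            raise ValueError("n_users and n_days must be >= 1")
        if self.profiles is not None and len(self.profiles) != self.n_users:
            raise ValueError("profiles, when given, must match n_users")


def _log_uniform_duration(rng: np.random.Generator) -> float:
    """Duration in seconds, log-uniform on [1, 30] minutes."""
    return 60.0 * float(np.exp(rng.uniform(np.log(1.0), np.log(30.0))))


def _day_events(
    profile: PersonaProfile,
    day: date,
    rng: np.random.Generator,
    scales: Sequence[ContextScale],
) -> list[SocialEvent]:
    cas = {scale(day) for scale in scales}
    midnight = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
    times: list[float] = []  # seconds since midnight
    for ca in sorted(profile.intervals):
        if ca not in cas:
            continue
        for (a, b) in profile.intervals[ca]:
            if rng.random() >= profile.p_active and profile.p_active < 1.0:
                continue
            shift_min = rng.uniform(-profile.jitter_minutes, profile.jitter_minutes)
            lo = max(a * 3600 + shift_min * 60, 0.0)
            hi = min(b * 3600 + shift_min * 60, _DAY_SECONDS - 1.0)
            if hi <= lo:
                continue
            n = rng.poisson(profile.events_per_interval_rate)
            times.extend(rng.uniform(lo, hi, size=n))
    n_noise = rng.poisson(profile.noise_rate)
    times.extend(rng.uniform(0.0, _DAY_SECONDS - 1.0, size=n_noise))
    events = []
    for t in sorted(times):
        start = midnight + timedelta(seconds=float(t))
        events.append(
            SocialEvent(
                activity_type="conversation",
                start=start,
                end=start + timedelta(seconds=_log_uniform_duration(rng)),
            )
        )
    return events


def generate_user(
    profile: PersonaProfile,
    n_days: int,
    start_date: date,
    seed: int | np.random.SeedSequence,
    scales: Sequence[ContextScale] = DEFAULT_SCALES,
) -> list[SocialEvent]:
    """Generate one user's stream over consecutive days, sorted by time."""
    rng = np.random.default_rng(seed)
    events: list[SocialEvent] = []
    for offset in range(n_days):
        events.extend(_day_events(profile, start_date + timedelta(days=offset), rng, scales))
    return events


def inject_routine_change(
    profile_a: PersonaProfile,
    profile_b: PersonaProfile,
    change_day: int,
    n_days: int,
    start_date: date = date(2024, 1, 1),
    seed: int | np.random.SeedSequence = 0,
    scales: Sequence[ContextScale] = DEFAULT_SCALES,
) -> list[SocialEvent]:
    """Stream whose days before ``change_day`` (1-based) follow persona A
    and whose days from ``change_day`` onward follow persona B, over a
    continuous date range."""
    if not 1 <= change_day <= n_days:
        raise ValueError(f"change_day must be in [1, {n_days}], got {change_day}")
    rng = np.random.default_rng(seed)
    events: list[SocialEvent] = []
    for offset in range(n_days):
        profile = profile_a if offset + 1 < change_day else profile_b
        events.extend(_day_events(profile, start_date + timedelta(days=offset), rng, scales))
    return events


def stability_gradient_profiles(
    n_users: int,
    seed: int | np.random.SeedSequence,
    context: str = "WEEKDAY",
    weekend_context: str = "WEEKEND",
) -> tuple[PersonaProfile, ...]:
    """Profiles spanning a wide realized-stability range.

    Users are spread over p_active in [0.3, 1.0], jitter in [45, 0] min
    and noise in [3, 0.5] events/day (least to most stable), each with
    randomly placed planted intervals per weekpart.
    """
    rng = np.random.default_rng(seed)
    p_actives = np.linspace(0.3, 1.0, n_users)
    jitters = np.linspace(45.0, 0.0, n_users)
    noises = np.linspace(3.0, 0.5, n_users)
    profiles = []
    for i in range(n_users):
        def random_intervals(n: int) -> tuple[tuple[float, float], ...]:
            starts = np.sort(rng.choice(np.arange(0.0, 22.0, 0.5), size=n, replace=False))
            ivs = []
            prev_end = 0.0
            for s in starts:
                a = max(float(s), prev_end)
                b = min(a + float(rng.uniform(1.0, 2.5)), 24.0)
                if b > a:
                    ivs.append((a, b))
                    prev_end = b
            return tuple(ivs)

        profiles.append(
            PersonaProfile(
                intervals={
                    context: random_intervals(3),
                    weekend_context: random_intervals(2),
                },
                events_per_interval_rate=4.0,
                p_active=float(p_actives[i]),
                jitter_minutes=float(jitters[i]),
                noise_rate=float(noises[i]),
            )
        )
    return tuple(profiles)


def generate_cohort(spec: CohortSpec) -> dict[str, list[SocialEvent]]:
    """Independent per-user streams; users named u01, u02, ...

    Per-user seeds are spawned from ``SeedSequence(spec.seed)``: child i
    drives user i's stream (and, when profiles are not supplied, a
    separate first child drives profile construction).
    """
    master = np.random.SeedSequence(spec.seed)
    if spec.profiles is None:
        profile_ss, *user_ss = master.spawn(spec.n_users + 1)
        profiles = stability_gradient_profiles(spec.n_users, profile_ss)
    else:
        profiles = spec.profiles
        user_ss = master.spawn(spec.n_users)
    return {
        f"u{i + 1:02d}": generate_user(profiles[i], spec.n_days, spec.start_date, user_ss[i])
        for i in range(spec.n_users)
    }


def write_cohort(
    streams: Mapping[str, list[SocialEvent]],
    out_dir: str | Path,
    dialect: str = "studentlife_csv",
    manifest: dict | None = None,
) -> Path:
    """Write one file per user plus a JSON provenance manifest."""
    from .events import write_jsonl, write_studentlife_csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".csv" if dialect == "studentlife_csv" else ".jsonl"
    writer = write_studentlife_csv if dialect == "studentlife_csv" else write_jsonl
    counts = {}
    for user, events in streams.items():
        counts[user] = writer(events, out_dir / f"{user}{suffix}")
    payload = {"dialect": dialect, "event_counts": counts}
    if manifest:
        payload["spec"] = manifest
    (out_dir / "manifest.json").write_text(json.dumps(payload, indent=2, default=str))
    return out_dir
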