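from datetime import date, datetime, timezone

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sociability import MinerParams, PersonaProfile, SlotGrid

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def grid() -> SlotGrid:
    return SlotGrid(0.5)


@pytest.fixture
def params(grid) -> MinerParams:
    return MinerParams(grid=grid)


@pytest.fixture
def stable_persona() -> PersonaProfile:
    """Noiseless persona expressing the same two weekday intervals daily."""
    return PersonaProfile(
        intervals={"WEEKDAY": ((9.0, 10.5), (20.0, 22.0)),
                   "WEEKEND": ((9.0, 10.5), (20.0, 22.0))},
        events_per_interval_rate=5.0,
        p_active=1.0,
        jitter_minutes=0.0,
        noise_rate=0.0,
    )


@pytest.fixture
def shifted_persona() -> PersonaProfile:
    """Noiseless persona with intervals slot-disjoint from stable_persona."""
    return PersonaProfile(
        intervals={"WEEKDAY": ((0.5, 2.0), (13.0, 14.5)),
                   "WEEKEND": ((0.5, 2.0), (13.0, 14.5))},
        events_per_interval_rate=5.0,
        p_active=1.0,
        jitter_minutes=0.0,
        noise_rate=0.0,
    )


def utc(y, mo, d, h=0, mi=0, s=0):
    return datetime(y, mo, d, h, mi, s, tzinfo=timezone.utc)


def planted_slot_set(intervals, grid: SlotGrid) -> frozenset[int]:
    """Slots overlapped by the planted clock-time intervals."""
    t = grid.slot_length_hours
    out: set[int] = set()
    for a, b in intervals:
        out |= set(range(int(np.floor(a / t)), int(np.ceil(b / t))))
    return frozenset(out)
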