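"""Slot counting, candidate filtering and pattern grouping."""

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sociability import (
    ContextCounterState,
    ContextPartitionMiner,
    MinerParams,
    SlotGrid,
    SocialEvent,
    enrich_event,
    extract_pattern,
    filter_candidate_slots,
    group_patterns,
    slot_threshold,
    update_counts,
)

from ._oracles import batch_patterns
from .conftest import utc


def _event(slot: int, cas=("MONDAY", "WEEKDAY")) -> SocialEvent:
    start = utc(2024, 1, 1) + timedelta(minutes=30 * slot)
    return SocialEvent(
        activity_type="conversation",
        start=start,
        slot=slot,
        context_attributes=frozenset(cas),
        date=start.date(),
    )


class TestCounting:
    def test_three_events_one_slot(self, grid):
        state = ContextCounterState.empty("MONDAY", grid)
        for _ in range(3):
            update_counts(state, _event(24))
        assert state.counts[24] == 3
        assert state.total == 3
        assert state.counts.sum() == 3

    def test_fan_out_to_all_event_cas(self, params):
        miner = ContextPartitionMiner(params)
        miner.process(_event(10, cas=("MONDAY", "WEEKDAY")))
        assert miner.state("MONDAY").total == 1
        assert miner.state("WEEKDAY").total == 1

    def test_initial_state_is_zero(self, grid):
        state = ContextCounterState.empty("MONDAY", grid)
        assert state.total == 0
        assert not state.counts.any()

    def test_wrong_partition_rejected(self, grid):
        state = ContextCounterState.empty("SUNDAY", grid)
        with pytest.raises(ValueError, match="do not include"):
            update_counts(state, _event(5))

    @given(slots=st.lists(st.integers(0, 47), max_size=200))
    def test_count_conservation(self, slots):
        state = ContextCounterState.empty("MONDAY", SlotGrid(0.5))
        for s in slots:
            update_counts(state, _event(s))
        assert state.counts.sum() == state.total == len(slots)


class TestThresholdAndFilter:
    def test_uniform_expectation_scaling(self, grid):
        assert slot_threshold(480, 1.0, grid) == 10.0

    def test_zero_total_or_theta(self, grid):
        assert slot_threshold(0, 2.5, grid) == 0.0
        assert slot_threshold(1000, 0.0, grid) == 0.0

    def test_boundary_count_retained(self):
        out = filter_candidate_slots(np.array([5, 12, 0, 9]), 9.0)
        assert out.tolist() == [0, 12, 0, 9]

    def test_zero_threshold_keeps_everything(self):
        counts = np.array([1, 0, 7, 3])
        assert filter_candidate_slots(counts, 0.0).tolist() == counts.tolist()

    def test_all_below_threshold(self):
        assert filter_candidate_slots(np.array([1, 2, 3]), 10.0).tolist() == [0, 0, 0]

    @given(
        counts=st.lists(st.integers(0, 50), min_size=1, max_size=48),
        sth=st.floats(0, 60, allow_nan=False),
    )
    def test_filter_is_idempotent_and_pure(self, counts, sth):
        arr = np.array(counts)
        once = filter_candidate_slots(arr, sth)
        assert arr.tolist() == counts  # input untouched
        assert filter_candidate_slots(once, sth).tolist() == once.tolist()


class TestGrouping:
    def test_two_runs_above_support(self):
        cs = np.zeros(48, dtype=int)
        cs[[1, 2]] = [10, 12]
        cs[[5, 6, 7]] = [8, 9, 7]
        runs = group_patterns(cs, phi=0.3, total=60)
        assert runs == [(1, 2), (5, 7)]  # sums 22 and 24, both >= 18

    def test_all_zero_no_patterns(self):
        assert group_patterns(np.zeros(48), 0.5, 0) == []

    def test_single_run_at_phi_one_boundary(self):
        cs = np.zeros(48, dtype=int)
        cs[[10, 11]] = [3, 4]
        assert group_patterns(cs, phi=1.0, total=7) == [(10, 11)]

    def test_wrap_midnight_merges_edge_runs(self):
        cs = np.zeros(48, dtype=int)
        cs[[46, 47, 0, 1]] = 5
        assert group_patterns(cs, 0.0, 20, wrap_midnight=False) == [(0, 1), (46, 47)]
        assert group_patterns(cs, 0.0, 20, wrap_midnight=True) == [(46, 1)]


class TestExtraction:
    def test_runs_convert_to_clock_intervals(self, grid):
        # 46 events in two dense blocks + 14 singletons spread thin enough
        # to fall below the candidate threshold 60/48 = 1.25
        state = ContextCounterState.empty("MONDAY", grid)
        for slot, n in [(1, 10), (2, 12), (5, 8), (6, 9), (7, 7)]:
            for _ in range(n):
                update_counts(state, _event(slot))
        for slot in range(9, 37, 2):
            update_counts(state, _event(slot))
        assert state.total == 60
        params = MinerParams(grid=grid, theta=1.0, phi=0.3)
        pattern = extract_pattern(state, params, extracted_at=date(2024, 1, 14))
        assert pattern.intervals == ((0.5, 1.5), (2.5, 4.0))
        assert pattern.slot_set == {1, 2, 5, 6, 7}
        assert pattern.support == 46

    def test_empty_state_empty_pattern(self, grid, params):
        state = ContextCounterState.empty("MONDAY", grid)
        pattern = extract_pattern(state, params)
        assert pattern.is_empty
        assert pattern.intervals == ()

    def test_uniform_counts_whole_day_single_run(self, grid):
        state = ContextCounterState(
            "MONDAY", np.full(48, 5, dtype=np.int64), total=240
        )
        params = MinerParams(grid=grid, theta=1.0, phi=0.0)
        pattern = extract_pattern(state, params)
        assert pattern.slot_set == frozenset(range(48))
        assert pattern.intervals == ((0.0, 24.0),)

    def test_json_serialization_shape(self, grid, params):
        state = ContextCounterState.empty("MONDAY", grid)
        for _ in range(10):
            update_counts(state, _event(19))
        obj = extract_pattern(state, params, date(2024, 1, 14)).to_json_dict()
        assert obj["intervals"] == [{"start": "09:30", "end": "10:00"}]
        assert obj["context"] == "MONDAY"
        assert obj["slot_set"] == [19]


class TestAgainstBatchOracle:
    @given(
        slots=st.lists(st.integers(0, 47), min_size=1, max_size=300),
        theta=st.floats(0.0, 3.0, allow_nan=False),
        phi=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_streaming_equals_batch(self, slots, theta, phi):
        grid = SlotGrid(0.5)
        params = MinerParams(grid=grid, theta=theta, phi=phi)
        state = ContextCounterState.empty("MONDAY", grid)
        for s in slots:
            update_counts(state, _event(s))
        pattern = extract_pattern(state, params)

        cs, runs = batch_patterns(slots, 48, theta, phi)
        sth = slot_threshold(len(slots), theta, grid)
        assert filter_candidate_slots(state.counts, sth).tolist() == cs
        assert sorted(pattern.slot_set) == sorted(i for r in runs for i in r)

    def test_monotonicity_in_theta_and_phi(self):
        rng = np.random.default_rng(42)
        slots = rng.integers(0, 48, size=200).tolist()
        grid = SlotGrid(0.5)
        state = ContextCounterState.empty("MONDAY", grid)
        for s in slots:
            update_counts(state, _event(int(s)))

        prev_candidates = None
        for theta in np.linspace(0, 3, 13):
            sth = slot_threshold(state.total, theta, grid)
            cand = set(np.flatnonzero(filter_candidate_slots(state.counts, sth)))
            if prev_candidates is not None:
                assert cand <= prev_candidates
            prev_candidates = cand

        prev_slots = None
        for phi in np.linspace(0, 1, 11):
            pattern = extract_pattern(state, MinerParams(grid=grid, theta=1.0, phi=phi))
            if prev_slots is not None:
                assert pattern.slot_set <= prev_slots
            prev_slots = pattern.slot_set
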