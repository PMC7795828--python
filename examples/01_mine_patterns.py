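"""Mine sociability patterns from a synthetic conversation stream.

A persona with two preferred conversation windows (09:00-10:30 and
20:00-22:00) is simulated for two weeks; the miner counts events per
30-minute slot for each context attribute and extracts the frequent
intervals.
"""

from datetime import date

from sociability import (
    ContextPartitionMiner,
    MinerParams,
    PersonaProfile,
    SlotGrid,
    enrich_event,
    generate_user,
)

grid = SlotGrid(0.5)
profile = PersonaProfile(
    intervals={"WEEKDAY": ((9.0, 10.5), (20.0, 22.0)),
               "WEEKEND": ((15.0, 17.0),)},
    events_per_interval_rate=5.0,
    p_active=0.9,
    jitter_minutes=10.0,
    noise_rate=1.0,
)
events = generate_user(profile, n_days=14, start_date=date(2024, 1, 1), seed=3)

miner = ContextPartitionMiner(MinerParams(grid=grid, theta=1.0, phi=0.3))
for event in events:
    miner.process(enrich_event(event, grid))

print(f"{len(events)} events over 14 days\n")
for context in ("WEEKDAY", "WEEKEND", "MONDAY"):
    pattern = miner.extract(context, extracted_at=date(2024, 1, 14))
    spans = ", ".join(f"{iv['start']}-{iv['end']}" for iv in
                      pattern.to_json_dict()["intervals"]) or "(none)"
    print(f"{context:8s} habitual intervals: {spans}  "
          f"(support {pattern.support} of {miner.state(context).total} events)")

# Each line is the set of time-of-day intervals in which this persona
# habitually socializes under that context; support counts the events
# that fall inside the pattern.
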