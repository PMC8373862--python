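"""The full measurement chain on a simulated day-1 cohort.

Simulates 4 participants' first measurement day, runs preprocessing, peak
detection, cycle-time extraction and the BRT-vs-REP coordination
difference, and prints the per-block group means: speed improves across
the five blocks of the day, the coordination difference does not.
"""

from digitcoord import SimulationConfig, analyze_trials, simulate_session

config = SimulationConfig(n_participants=4, days=(1,), seed=7)
session = simulate_session(config)
result = analyze_trials(session.trials)

per_block = result.per_block
summary = per_block.groupby("block")[["cycle_time_brt", "cycle_time_rep", "coord_diff"]].mean()
print("Group means by day-1 block:")
print(summary.round(3))
print(f"\nexclusions logged: {len(result.exclusions)}")

improvement = summary["cycle_time_brt"].iloc[0] - summary["cycle_time_brt"].iloc[-1]
print(
    f"\nReading: cycle time falls by ~{improvement:.2f} s from block 1 to"
    "\nblock 5 (motor performance improves within the first day), while the"
    "\ncoordination difference stays near its initial level (the internal"
    "\nrepresentation of the movement has not yet sharpened). The"
    "\nreproduction task is consistently slower than the real task."
)
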