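"""Generate a small synthetic cohort and inspect its ground truth.

Builds a 2-participant, 2-measurement-day dataset (5 blocks x 12 trials
each day: one reproduction trial, ten ball-rotation trials, one
reproduction trial), writes it as tracker CSVs with a manifest, and prints
the programmed truth: cycle times shorten with practice while the
reproduction phase error only decays across days.
"""

from pathlib import Path

from digitcoord import SimulationConfig, simulate_session

config = SimulationConfig(n_participants=2, days=(1, 8), seed=1)
session = simulate_session(config)

outdir = Path("scratch/example_dataset")
manifest = session.write(outdir)
print(f"wrote {len(session.trials)} trials under {outdir} (manifest: {manifest.name})")

truth = session.truth_trials
brt = truth[truth.task == "BRT"]
rep = truth[truth.task == "REP"]

print("\nTrue BRT cycle time (s) by day and block, participant P01:")
p1 = brt[brt.participant_id == "P01"]
print(p1.groupby(["day", "block"])["block_cycle_time"].first().round(3).unstack())

print("\nTrue reproduction phase error (cycle fractions) by day, P01:")
print(rep[rep.participant_id == "P01"].groupby("day")["delta_target"].first().round(3))

print(
    "\nReading: cycle time drops already across day-1 blocks (performance"
    "\nimproves immediately), while delta is constant within a day and only"
    "\nshrinks from day 1 to day 8 (recognition improves across weeks)."
)
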