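"""The inferential layer on a full five-week simulated cohort.

Simulates the complete 12-participant protocol (days 1, 8, 15, 22, 29),
analyzes it, and runs the statistics battery: rmANOVAs with
Greenhouse-Geisser handling across days and across day-1 blocks,
Bonferroni post-hocs, day-1 correlation between speed and coordination
difference, and the signed-rank comparison of normalized day-1
improvements. Takes a minute or two.
"""

from digitcoord import SimulationConfig, analyze_trials, simulate_session
from digitcoord.pipeline import format_report, run_stats_battery

config = SimulationConfig(seed=11)  # full default protocol
session = simulate_session(config)
result = analyze_trials(session.trials)
report = run_stats_battery(result.per_block, result.per_day)

wanted = (
    "cycle_time_brt:across_days",
    "cycle_time_brt:day1_blocks",
    "coord_diff:across_days",
    "coord_diff:day1_blocks",
    "pearson_cycle_vs_coord:day1",
    "normalized_improvement_cycle_vs_coord:day1",
)
subset = report[report.analysis.isin(wanted)]
print(format_report(subset))

print(
    "Reading: both measures shrink across days (significant day effects),"
    "\nbut within day 1 only the cycle time shows a block effect — the"
    "\ndissociation between acquiring a motor skill and being able to"
    "\naccess it. z > 0 in the signed-rank line says speed improved more"
    "\nthan coordination accuracy on day 1."
)
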