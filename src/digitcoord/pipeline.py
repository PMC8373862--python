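"""End-to-end orchestration: trials -> session tables -> statistics report.

``analyze_trials`` runs the full measurement chain on any collection of
:class:`~digitcoord.trajio.TrialRecording` objects — dropout repair,
bandpass filtering, extension-peak detection, per-block cycle times for
both tasks, the block-typical ball-rotation pattern and the BRT–REP
coordination difference — and returns tidy per-block and per-day tables.

``run_stats_battery`` applies the inferential layer to those tables:
repeated-measures ANOVAs across days and across day-1 blocks for both
outcome measures, Bonferroni-corrected adjacent post-hoc contrasts,
the day-1 / final-day correlations between performance and coordination
difference, the learning-rate correlations, and the signed-rank comparison
of normalized day-1 improvements.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from . import coordination, kinematics, preprocess, stats
from .trajio import KEY_COLUMNS, PAIR_COLUMNS, SESSION_COLUMNS, TrialRecording


@dataclass
class AnalysisConfig:
    """Every tunable of the measurement chain, with its default.

    Mirrors the configuration keys accepted in YAML form by the command
    line (``filter.low_hz`` etc. — see :mod:`digitcoord.cli`).
    """

    # gap handling
    conf_threshold: float = preprocess.DEFAULT_CONF_THRESHOLD
    max_gap_frames: int = preprocess.DEFAULT_MAX_GAP
    # bandpass
    low_hz: float = 0.5
    high_hz: float = 5.0
    order: int = 2
    zero_phase: bool = True
    # peak detection
    min_period_s: float = kinematics.DEFAULT_MIN_PERIOD
    min_prominence_frac: float = kinematics.DEFAULT_MIN_PROMINENCE_FRAC
    # extension signal
    extension_mode: str = "axis"  # axis | pca | radial
    extension_axis: tuple[float, float] = (0.0, 1.0)
    # coordination
    circular: bool = True


@dataclass
class SessionResult:
    """Output of the measurement chain on one dataset."""

    per_block: pd.DataFrame  # session-table rows (one per participant/day/block)
    per_day: pd.DataFrame  # block means per participant/day
    exclusions: List[dict] = field(default_factory=list)


def _process_trial(trial: TrialRecording, config: AnalysisConfig):
    """Filter one trial and extract its five peak trains; None if unusable."""
    filtered = preprocess.preprocess_trial(
        trial,
        conf_threshold=config.conf_threshold,
        max_gap=config.max_gap_frames,
        low=config.low_hz,
        high=config.high_hz,
        order=config.order,
        zero_phase=config.zero_phase,
    )
    if filtered is None:
        return None
    return kinematics.trial_peak_trains(
        filtered,
        mode=config.extension_mode,
        axis=config.extension_axis,
        min_period=config.min_period_s,
        min_prominence_frac=config.min_prominence_frac,
    )


def analyze_trials(
    trials: Iterable[TrialRecording],
    config: AnalysisConfig | None = None,
) -> SessionResult:
    """Run the full measurement chain over a collection of trials.

    Per (participant, day, block): the cycle time of each task is the
    median over trials of the per-trial median thumb cycle duration; the
    coordination difference compares the reproduction trials' per-cycle
    pair phases with the block-typical ball-rotation pattern.  Unusable
    trials (tracking gaps, too few peaks) are excluded and logged, never
    silently dropped.
    """
    config = config or AnalysisConfig()
    exclusions: List[dict] = []
    groups: Dict[tuple, dict] = {}

    for trial in trials:
        key = (trial.participant_id, trial.day, trial.block)
        slot = groups.setdefault(key, {"BRT": [], "REP": []})
        peaks = _process_trial(trial, config)
        if peaks is None:
            exclusions.append(
                dict(
                    participant_id=trial.participant_id,
                    day=trial.day,
                    block=trial.block,
                    trial_index=trial.trial_index,
                    task=trial.task,
                    reason="unusable tracking gap",
                )
            )
            continue
        slot[trial.task].append((trial.trial_index, peaks))

    rows = []
    for key in sorted(groups):
        pid, day, block = key
        slot = groups[key]
        row: dict = dict(participant_id=pid, day=day, block=block)

        cycle_medians: Dict[str, List[float]] = {"BRT": [], "REP": []}
        for task in ("BRT", "REP"):
            for trial_index, peaks in slot[task]:
                try:
                    cycle_medians[task].append(
                        kinematics.cycle_times(peaks["thumb"]).trial_median
                    )
                except kinematics.TooFewPeaksError as exc:
                    exclusions.append(
                        dict(
                            participant_id=pid,
                            day=day,
                            block=block,
                            trial_index=trial_index,
                            task=task,
                            reason=str(exc),
                        )
                    )
        row["cycle_time_brt"] = (
            kinematics.block_cycle_time(cycle_medians["BRT"]) if cycle_medians["BRT"] else np.nan
        )
        row["cycle_time_rep"] = (
            kinematics.block_cycle_time(cycle_medians["REP"]) if cycle_medians["REP"] else np.nan
        )

        brt_peaks = [p for _, p in slot["BRT"]]
        rep_peaks = [p for _, p in slot["REP"]]
        if brt_peaks and rep_peaks:
            typical = coordination.typical_pattern(brt_peaks, context=(pid, day, block, "BRT"))
            try:
                diff = coordination.coordination_difference(
                    rep_peaks, typical, circular=config.circular, context=key
                )
                row["coord_diff"] = diff.mean_diff
                for label in PAIR_COLUMNS:
                    row[label] = diff.pair_diffs.get(label, np.nan)
                for label in diff.dropped_pairs:
                    exclusions.append(
                        dict(
                            participant_id=pid,
                            day=day,
                            block=block,
                            trial_index=None,
                            task="REP",
                            reason=f"pair {label} had no matchable REP cycle",
                        )
                    )
            except ValueError as exc:
                row["coord_diff"] = np.nan
                exclusions.append(
                    dict(
                        participant_id=pid,
                        day=day,
                        block=block,
                        trial_index=None,
                        task="REP",
                        reason=str(exc),
                    )
                )
        else:
            row["coord_diff"] = np.nan
            exclusions.append(
                dict(
                    participant_id=pid,
                    day=day,
                    block=block,
                    trial_index=None,
                    task="both",
                    reason="missing BRT or REP trials for coordination difference",
                )
            )
        for label in PAIR_COLUMNS:
            row.setdefault(label, np.nan)
        rows.append(row)

    per_block = pd.DataFrame(rows, columns=list(SESSION_COLUMNS))
    value_cols = [c for c in SESSION_COLUMNS if c not in KEY_COLUMNS]
    per_day = (
        per_block.groupby(["participant_id", "day"], as_index=False)[value_cols].mean()
        if len(per_block)
        else pd.DataFrame(columns=["participant_id", "day", *value_cols])
    )
    return SessionResult(per_block=per_block, per_day=per_day, exclusions=exclusions)


# ---------------------------------------------------------------------------
# Statistics battery
# ---------------------------------------------------------------------------


def _pivot(table: pd.DataFrame, index: str, column: str, value: str) -> pd.DataFrame:
    wide = table.pivot(index="participant_id", columns=column, values=value).sort_index()
    return wide.reindex(sorted(wide.columns), axis=1)


def _adjacent_posthoc(wide: pd.DataFrame, family_m: int, label: str, rows: list) -> None:
    levels = list(wide.columns)
    for a, b in zip(levels[:-1], levels[1:]):
        sub = wide[[a, b]].dropna()
        try:
            res = stats.paired_t(sub[a].to_numpy(), sub[b].to_numpy(), family_m=family_m)
        except ValueError as exc:
            rows.append(dict(analysis=f"{label}:{a}_vs_{b}", statistic="skipped", value=str(exc)))
            continue
        for name, val in (
            ("t", res.t),
            ("df", res.df),
            ("p", res.p),
            ("d", res.d),
            ("alpha_adjusted", res.alpha_adjusted),
        ):
            rows.append(dict(analysis=f"{label}:{a}_vs_{b}", statistic=name, value=val))


def _rm_anova_rows(wide: pd.DataFrame, label: str, rows: list) -> stats.RmAnovaResult | None:
    wide = wide.dropna()
    if len(wide) < 2 or wide.shape[1] < 2:
        rows.append(dict(analysis=label, statistic="skipped", value="insufficient participants"))
        return None
    res = stats.rm_anova(wide.to_numpy())
    for name, val in (
        ("F", res.F),
        ("df1", res.df1),
        ("df2", res.df2),
        ("p", res.p),
        ("partial_eta_sq", res.partial_eta_sq),
        ("mauchly_W", res.mauchly_W),
        ("mauchly_p", res.mauchly_p),
        ("gg_epsilon", res.gg_epsilon),
        ("gg_corrected", float(res.corrected)),
    ):
        rows.append(dict(analysis=label, statistic=name, value=val))
    return res


def run_stats_battery(
    per_block: pd.DataFrame,
    per_day: pd.DataFrame,
    posthoc_family_m: int = 4,
) -> pd.DataFrame:
    """The full inferential analysis set on session tables.

    Returns a tidy frame of (analysis, statistic, value) rows.  The
    post-hoc family size of 4 corresponds to adjacent-level contrasts among
    five days or five blocks at family alpha .05, i.e. a per-test threshold
    of .0125.  Analyses whose preconditions fail (too few participants,
    zero-variance contrasts) are reported as skipped, not dropped.
    """
    rows: list = []
    days = sorted(per_day["day"].unique())
    first_day, last_day = (days[0], days[-1]) if days else (None, None)
    day1_blocks = per_block[per_block["day"] == first_day] if days else per_block.iloc[:0]
    lastday_blocks = per_block[per_block["day"] == last_day] if days else per_block.iloc[:0]

    for measure in ("cycle_time_brt", "coord_diff", "cycle_time_rep"):
        wide_days = _pivot(per_day, "participant_id", "day", measure)
        res = _rm_anova_rows(wide_days, f"{measure}:across_days", rows)
        if res is not None:
            _adjacent_posthoc(
                wide_days.dropna(), posthoc_family_m, f"{measure}:across_days", rows
            )
        for day_label, blocks in (("day1", day1_blocks), ("final_day", lastday_blocks)):
            if not len(blocks):
                continue
            wide_blocks = _pivot(blocks, "participant_id", "block", measure)
            res_b = _rm_anova_rows(wide_blocks, f"{measure}:{day_label}_blocks", rows)
            if res_b is not None:
                _adjacent_posthoc(
                    wide_blocks.dropna(), posthoc_family_m, f"{measure}:{day_label}_blocks", rows
                )

    # correlations between performance and coordination difference
    for day_label, day in (("day1", first_day), ("final_day", last_day)):
        if day is None:
            continue
        sub = per_day[per_day["day"] == day].dropna(subset=["cycle_time_brt", "coord_diff"])
        label = f"pearson_cycle_vs_coord:{day_label}"
        if len(sub) < 3:
            rows.append(dict(analysis=label, statistic="skipped", value="insufficient n"))
            continue
        try:
            res = stats.pearson(sub["cycle_time_brt"], sub["coord_diff"])
        except ValueError as exc:
            rows.append(dict(analysis=label, statistic="skipped", value=str(exc)))
            continue
        for name, val in (("r", res.r), ("p", res.p), ("n", res.n)):
            rows.append(dict(analysis=label, statistic=name, value=val))

    # learning rate (block 1 - block 5 of cycle time) on day 1: correlations
    # with the day-1 coordination difference and with initial performance
    if len(day1_blocks):
        wide = _pivot(day1_blocks, "participant_id", "block", "cycle_time_brt")
        if {1, 5}.issubset(set(wide.columns)):
            lr = (wide[1] - wide[5]).rename("learning_rate")
            day1_coord = per_day[per_day["day"] == first_day].set_index("participant_id")[
                "coord_diff"
            ]
            pairs = (
                ("learning_rate_vs_coord:day1", lr, day1_coord),
                ("learning_rate_vs_initial:day1", lr, wide[1]),
            )
            for label, xs, ys in pairs:
                joined = pd.concat([xs, ys], axis=1).dropna()
                if len(joined) < 3:
                    rows.append(dict(analysis=label, statistic="skipped", value="insufficient n"))
                    continue
                try:
                    res = stats.pearson(joined.iloc[:, 0], joined.iloc[:, 1])
                except ValueError as exc:
                    rows.append(dict(analysis=label, statistic="skipped", value=str(exc)))
                    continue
                for name, val in (("r", res.r), ("p", res.p), ("n", res.n)):
                    rows.append(dict(analysis=label, statistic=name, value=val))

    # normalized day-1 improvements: speed vs coordination difference
    if len(day1_blocks):
        wide_cycle = _pivot(day1_blocks, "participant_id", "block", "cycle_time_brt")
        wide_coord = _pivot(day1_blocks, "participant_id", "block", "coord_diff")
        label = "normalized_improvement_cycle_vs_coord:day1"
        if {1, 5}.issubset(wide_cycle.columns) and {1, 5}.issubset(wide_coord.columns):
            joined = pd.concat(
                [wide_cycle[[1, 5]].add_prefix("cyc"), wide_coord[[1, 5]].add_prefix("crd")],
                axis=1,
            ).dropna()
            if len(joined) >= 2:
                try:
                    res = stats.normalized_improvement_compare(
                        (joined["cyc1"].to_numpy(), joined["cyc5"].to_numpy()),
                        (joined["crd1"].to_numpy(), joined["crd5"].to_numpy()),
                    )
                    for name, val in (("z", res.z), ("p", res.p), ("d", res.d), ("n", res.n)):
                        rows.append(dict(analysis=label, statistic=name, value=val))
                except ValueError as exc:
                    rows.append(dict(analysis=label, statistic="skipped", value=str(exc)))
            else:
                rows.append(dict(analysis=label, statistic="skipped", value="insufficient n"))

    return pd.DataFrame(rows, columns=["analysis", "statistic", "value"])


def format_report(results: pd.DataFrame) -> str:
    """Human-readable rendering of the battery output."""
    lines = []
    for analysis, group in results.groupby("analysis", sort=False):
        parts = []
        for row in group.itertuples(index=False):
            if row.statistic == "skipped":
                parts.append(f"skipped ({row.value})")
            else:
                try:
                    parts.append(f"{row.statistic}={float(row.value):.4g}")
                except (TypeError, ValueError):
                    parts.append(f"{row.statistic}={row.value}")
        lines.append(f"{analysis}: " + ", ".join(parts))
    return "\n".join(lines) + "\n"
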