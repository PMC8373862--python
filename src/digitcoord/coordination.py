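"""Relative phase, typical coordination patterns, and the BRT–REP difference.

The coordination measure is built on the discrete relative phase between two
digits: with f the reference digit and h the other, the phase of h's peak
inside f's i-th cycle is

    phi_hf = (t_h - t_f,i) / (t_f,i+1 - t_f,i)   (mod 1)

so phi = 0 means the two digits peak in phase and phi = 0.5 antiphase.  The
reduction modulo 1 keeps every phase in [0, 1), consistent with those
anchors, whichever digit happens to lead.

A block's *typical pattern* for the ball-rotation task is the vector of
circular medians of phi over all pooled BRT cycles, one entry per each of
the 10 unordered digit pairs (thumb-index, thumb-middle, ..., ring-little).
The *coordination difference* — the recognition-capability measure — then
compares each reproduction-task cycle's phase against the block-typical
median on the circle, takes the per-pair median of those distances, and
averages the 10 pairs.  Distances use the circular metric
d(a, b) = min(|a-b|, 1-|a-b|) in [0, 0.5]: a phase of 0.95 and one of 0.05
describe nearly identical timing, and a linear |a-b| = 0.9 would break the
topology of phase.  (A ``circular=False`` escape hatch reproduces the naive
linear reading for sensitivity analysis.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinematics import PeakTrain
from .trajio import DIGIT_NUMBER, DIGITS, PAIR_COLUMNS, PAIRS, pair_label


def circular_distance(a, b):
    """Distance on the unit circle (cycle fraction), in [0, 0.5]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 1.0
    return np.minimum(d, 1.0 - d)


def circular_median(values: Sequence[float]) -> float:
    """Median of phases in [0, 1) under the circular metric.

    Cuts the circle at its largest empty arc, unwraps the sample to a line
    segment, and takes the ordinary median there (even counts: midpoint of
    the two central values).  For samples concentrated away from the 0/1
    seam this equals the linear median; the result minimises the sum of
    circular distances to the sample, with the largest-gap cut (first
    occurrence on ties) fixing the convention among tied minimisers.
    """
    v = np.sort(np.asarray(values, dtype=float) % 1.0)
    if v.size == 0:
        raise ValueError("circular_median of empty sequence")
    if v.size == 1:
        return float(v[0])
    gaps = np.diff(np.concatenate([v, v[:1] + 1.0]))
    cut = int(np.argmax(gaps))  # gap between v[cut] and the next value
    if cut == v.size - 1:  # largest gap spans the seam: plain median works
        unwrapped = v
    else:
        unwrapped = np.concatenate([v[cut + 1 :], v[: cut + 1] + 1.0])
    return float(np.median(unwrapped) % 1.0)


@dataclass
class RelativePhaseSeries:
    """Per-cycle relative phases of one digit pair in one trial."""

    pair: tuple[str, str]  # (reference f, other h)
    phi_values: np.ndarray  # in [0, 1)
    n_dropped_cycles: int = 0  # reference cycles with 0 or >= 2 matches


def relative_phase(ref: PeakTrain, other: PeakTrain) -> RelativePhaseSeries:
    """Relative phase of *other*'s peaks within *ref*'s cycles.

    For each reference cycle [t_f,i, t_f,i+1): if exactly one peak of the
    other digit falls inside, phi = (t_h - t_f,i) / cycle, reduced modulo 1
    into [0, 1).  Cycles containing zero or multiple peaks of the other
    digit are dropped and counted, never resolved arbitrarily — missed or
    spurious peaks should not invent a correspondence.
    """
    if ref.n < 2:
        return RelativePhaseSeries(pair=(ref.digit, other.digit), phi_values=np.empty(0))
    tf = ref.times
    th = other.times
    phis: List[float] = []
    dropped = 0
    # count other-digit peaks per half-open reference cycle
    pos = np.searchsorted(th, tf, side="left")
    for i in range(tf.size - 1):
        lo, hi = pos[i], pos[i + 1]
        if hi - lo != 1:
            dropped += 1
            continue
        phi = (th[lo] - tf[i]) / (tf[i + 1] - tf[i])
        phis.append(phi % 1.0)
    return RelativePhaseSeries(
        pair=(ref.digit, other.digit),
        phi_values=np.asarray(phis, dtype=float),
        n_dropped_cycles=dropped,
    )


def trial_pair_phases(peaks: Mapping[str, PeakTrain]) -> Dict[str, np.ndarray]:
    """Relative-phase values for all 10 digit pairs of one trial.

    The lower-numbered digit of each pair is the reference (thumb-first
    convention); keys are the canonical pair labels ``d1_d2`` ... ``d4_d5``.
    """
    out: Dict[str, np.ndarray] = {}
    for f, h in PAIRS:
        out[pair_label(f, h)] = relative_phase(peaks[f], peaks[h]).phi_values
    return out


@dataclass
class CoordinationPattern:
    """Circular-median relative phase per digit pair for one block/task."""

    context: tuple  # (participant_id, day, block, task)
    pair_medians: Dict[str, float]
    n_cycles: Dict[str, int] = field(default_factory=dict)
    complete: bool = True

    def as_vector(self) -> np.ndarray:
        return np.asarray([self.pair_medians[p] for p in PAIR_COLUMNS], dtype=float)


@dataclass
class CoordinationDifference:
    """BRT–REP coordination difference for one block."""

    context: tuple  # (participant_id, day, block)
    pair_diffs: Dict[str, float]  # circular distances in [0, 0.5]
    mean_diff: float
    dropped_pairs: List[str] = field(default_factory=list)


def typical_pattern(
    brt_trials: Iterable[Mapping[str, PeakTrain]],
    context: tuple = (),
) -> CoordinationPattern:
    """Block-typical BRT pattern: pooled circular medians over the block.

    Pools per-cycle phi values across all the block's ball-rotation trials
    for each pair and takes the circular median.  A pair with zero pooled
    cycles leaves the pattern flagged incomplete.
    """
    pooled: Dict[str, List[np.ndarray]] = {p: [] for p in PAIR_COLUMNS}
    n_trials = 0
    for peaks in brt_trials:
        n_trials += 1
        for label, phis in trial_pair_phases(peaks).items():
            if phis.size:
                pooled[label].append(phis)
    if n_trials == 0:
        raise ValueError("typical_pattern needs at least one BRT trial")
    medians: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    complete = True
    for label in PAIR_COLUMNS:
        vals = np.concatenate(pooled[label]) if pooled[label] else np.empty(0)
        counts[label] = int(vals.size)
        if vals.size == 0:
            medians[label] = float("nan")
            complete = False
        else:
            medians[label] = circular_median(vals)
    return CoordinationPattern(
        context=tuple(context), pair_medians=medians, n_cycles=counts, complete=complete
    )


def coordination_difference_from_phases(
    rep_pair_phases: Mapping[str, np.ndarray],
    typical: CoordinationPattern,
    circular: bool = True,
    context: tuple = (),
) -> CoordinationDifference:
    """Coordination difference from already-extracted REP phase values.

    For each pair: the per-REP-cycle (circular) distance between the REP
    phase and the block-typical BRT median, then the median of those
    distances; the block measure is the mean over the 10 per-pair medians.
    Pairs with no REP cycles are dropped with a record, and the mean runs
    over the remaining pairs.
    """
    pair_diffs: Dict[str, float] = {}
    dropped: List[str] = []
    for label in PAIR_COLUMNS:
        ref = typical.pair_medians.get(label, float("nan"))
        vals = np.asarray(rep_pair_phases.get(label, ()), dtype=float)
        if vals.size == 0 or not np.isfinite(ref):
            dropped.append(label)
            continue
        if circular:
            dists = circular_distance(vals, ref)
        else:
            dists = np.abs(vals - ref)
        pair_diffs[label] = float(np.median(dists))
    if not pair_diffs:
        raise ValueError("no digit pair has any matchable REP cycle")
    mean_diff = float(np.mean(list(pair_diffs.values())))
    return CoordinationDifference(
        context=tuple(context), pair_diffs=pair_diffs, mean_diff=mean_diff, dropped_pairs=dropped
    )


def coordination_difference(
    rep_trials: Iterable[Mapping[str, PeakTrain]],
    typical: CoordinationPattern,
    circular: bool = True,
    context: tuple = (),
) -> CoordinationDifference:
    """BRT–REP coordination difference for one block from REP peak trains.

    Pools the reproduction trials' per-cycle phases per pair, then delegates
    to :func:`coordination_difference_from_phases`.
    """
    pooled: Dict[str, List[np.ndarray]] = {p: [] for p in PAIR_COLUMNS}
    n_trials = 0
    for peaks in rep_trials:
        n_trials += 1
        for label, phis in trial_pair_phases(peaks).items():
            if phis.size:
                pooled[label].append(phis)
    if n_trials == 0:
        raise ValueError("coordination_difference needs at least one REP trial")
    phases = {
        label: (np.concatenate(v) if v else np.empty(0)) for label, v in pooled.items()
    }
    return coordination_difference_from_phases(
        phases, typical, circular=circular, context=context
    )


def per_pair_table(diffs: Iterable[CoordinationDifference]) -> pd.DataFrame:
    """Tidy table of the 10 per-pair differences across blocks/days.

    Pure reshaping: one row per CoordinationDifference context, one column
    per pair plus the mean.
    """
    rows = []
    for diff in diffs:
        pid, day, block = diff.context
        row = {"participant_id": pid, "day": day, "block": block, "coord_diff": diff.mean_diff}
        for label in PAIR_COLUMNS:
            row[label] = diff.pair_diffs.get(label, float("nan"))
        rows.append(row)
    cols = ["participant_id", "day", "block", "coord_diff", *PAIR_COLUMNS]
    return pd.DataFrame(rows, columns=cols)
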