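"""Trajectory conditioning: tracker-dropout repair and bandpass filtering.

Raw fingertip series are conditioned in two steps before any kinematic
quantity is computed:

1. :func:`fill_low_confidence` — frames whose tracker confidence falls below
   a threshold are linearly interpolated from the flanking good frames, but
   only across short gaps; a long gap, or a gap touching a trial boundary,
   flags the whole trial as unusable (no extrapolation is ever attempted).
2. :func:`bandpass` — a 0.5–5 Hz 2nd-order Butterworth bandpass, applied
   forward and backward (zero-phase).  The analysis downstream lives
   entirely in peak *timing* across digits, and a causal filter would add a
   frequency-dependent lag to every series; forward–backward application
   keeps peak times in place at the cost of doubling the effective order,
   which is inconsequential because both tasks are filtered identically.

Both x and y are filtered for every digit; the scalar "extension" signal is
derived later, so preprocessing stays task-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy import signal as sp_signal

from .trajio import DIGITS, TrialRecording

#: Default tracker-confidence threshold below which a frame is a dropout.
DEFAULT_CONF_THRESHOLD = 0.9

#: Default longest gap (frames) that may be bridged by interpolation: 0.1 s
#: at 300 Hz, the tracker-community convention for brief occlusions.
DEFAULT_MAX_GAP = 30


@dataclass
class FilterSpec:
    """Bandpass configuration recorded into every FilteredTrial."""

    low_hz: float = 0.5
    high_hz: float = 5.0
    order: int = 2
    zero_phase: bool = True


@dataclass
class GapFillReport:
    """Outcome of dropout repair for one trial."""

    usable: bool
    reason: str | None
    #: per digit: list of (start, stop) frame spans (stop exclusive) filled
    filled_spans: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)


@dataclass
class FilteredTrial:
    """A TrialRecording whose series have been bandpass-filtered.

    Exposes the same array access as the recording it wraps so that the
    kinematics layer accepts either.
    """

    trial: TrialRecording
    filter_spec: FilterSpec
    gap_report: GapFillReport | None = None

    @property
    def x(self):
        return self.trial.x

    @property
    def y(self):
        return self.trial.y

    @property
    def confidence(self):
        return self.trial.confidence

    @property
    def frame_rate(self):
        return self.trial.frame_rate

    @property
    def duration(self):
        return self.trial.duration

    @property
    def digits(self):
        return self.trial.digits

    @property
    def times(self):
        return self.trial.times


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Contiguous True runs of a boolean mask as (start, stop) spans."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def fill_low_confidence(
    trial: TrialRecording,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[TrialRecording, GapFillReport]:
    """Repair short tracker dropouts by linear interpolation.

    Frames with ``confidence < conf_threshold`` (or non-finite positions)
    are interpolated from the nearest good frames on both sides when the
    contiguous gap is at most *max_gap* frames.  Longer gaps, or gaps
    touching either trial boundary, mark the trial unusable.

    Returns the repaired recording (confidence of filled frames set to the
    threshold value so that repairs remain identifiable) and a
    :class:`GapFillReport` listing every filled span.
    """
    if not 0.0 <= conf_threshold <= 1.0:
        raise ValueError("conf_threshold must be in [0, 1]")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = trial.copy_with()
    spans_by_digit: Dict[str, List[Tuple[int, int]]] = {}
    for d in DIGITS:
        bad = (
            (out.confidence[d] < conf_threshold)
            | ~np.isfinite(out.x[d])
            | ~np.isfinite(out.y[d])
        )
        spans = _runs(bad)
        filled: List[Tuple[int, int]] = []
        for start, stop in spans:
            length = stop - start
            if start == 0 or stop == out.n_frames:
                return trial, GapFillReport(
                    usable=False,
                    reason=f"gap of {length} frames touches trial boundary (digit {d})",
                    filled_spans=spans_by_digit,
                )
            if length > max_gap:
                return trial, GapFillReport(
                    usable=False,
                    reason=f"gap of {length} frames exceeds max_gap={max_gap} (digit {d})",
                    filled_spans=spans_by_digit,
                )
            idx = np.arange(start, stop)
            for series in (out.x[d], out.y[d]):
                series[idx] = np.interp(idx, [start - 1, stop], [series[start - 1], series[stop]])
            out.confidence[d][idx] = conf_threshold
            filled.append((start, stop))
        if filled:
            spans_by_digit[d] = filled
    return out, GapFillReport(usable=True, reason=None, filled_spans=spans_by_digit)


def bandpass(
    trial: TrialRecording,
    low: float = 0.5,
    high: float = 5.0,
    order: int = 2,
    zero_phase: bool = True,
    gap_report: GapFillReport | None = None,
) -> FilteredTrial:
    """Butterworth-bandpass every digit's x and y series.

    The default is the 0.5–5 Hz 2nd-order design; with ``zero_phase=True``
    (the default) it is applied forward and backward so peak times do not
    shift.  Edges are handled by odd-reflective padding of one low-corner
    period (``frame_rate / low`` samples, capped at series length - 1)
    before filtering — 8-s trials are short relative to a 0.5 Hz corner.

    Raises ``ValueError`` on non-finite samples (run
    :func:`fill_low_confidence` first) or an invalid passband.
    """
    fr = trial.frame_rate
    if not (0 < low < high < fr / 2):
        raise ValueError(f"require 0 < low < high < Nyquist; got {low}, {high} at {fr} Hz")
    sos = sp_signal.butter(order, [low, high], btype="bandpass", fs=fr, output="sos")
    n = trial.n_frames
    padlen = int(min(n - 1, round(fr / low)))
    out = trial.copy_with()
    for d in DIGITS:
        for series in (out.x, out.y):
            arr = series[d]
            if not np.all(np.isfinite(arr)):
                raise ValueError(
                    f"non-finite samples in digit {d!r}; run fill_low_confidence first"
                )
            if zero_phase:
                series[d] = sp_signal.sosfiltfilt(sos, arr, padtype="odd", padlen=padlen)
            else:
                padded = np.concatenate(
                    [2 * arr[0] - arr[padlen:0:-1], arr, 2 * arr[-1] - arr[-2 : -padlen - 2 : -1]]
                )
                series[d] = sp_signal.sosfilt(sos, padded)[padlen : padlen + n]
    return FilteredTrial(
        trial=out,
        filter_spec=FilterSpec(low_hz=low, high_hz=high, order=order, zero_phase=zero_phase),
        gap_report=gap_report,
    )


def preprocess_trial(
    trial: TrialRecording,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    max_gap: int = DEFAULT_MAX_GAP,
    low: float = 0.5,
    high: float = 5.0,
    order: int = 2,
    zero_phase: bool = True,
) -> FilteredTrial | None:
    """Gap-fill then bandpass one trial; ``None`` if the trial is unusable."""
    repaired, report = fill_low_confidence(trial, conf_threshold, max_gap)
    if not report.usable:
        return None
    return bandpass(repaired, low, high, order, zero_phase, gap_report=report)
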