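"""Extension-peak detection and the cycle-time performance measure.

One "cycle" of the ball-rotation movement is delimited by two consecutive
maximum extensions of the thumb, so the per-trial performance measure is
the median of the successive differences between thumb extension-peak
times.  The aggregation hierarchy follows the measurement protocol:

    per cycle  →  median per trial  →  median per block  →  mean per day

The 2-D fingertip trajectory is first reduced to a scalar *extension
signal* whose local maxima are the "maximum extensions".  Three reductions
are provided, because camera orientation varies between setups:

* ``axis`` (default) — signed projection onto a fixed image axis, default
  +y, the vertical for a palm-up camera view;
* ``pca`` — projection onto the first principal direction of that digit's
  trajectory within the trial;
* ``radial`` — distance from the trial centroid of the digit.

Peaks are local maxima with prominence of at least a configured fraction of
the signal's standard deviation and spacing of at least ``min_period``
seconds; the discrete maximum is refined to sub-frame precision by a
3-point quadratic fit, since relative phase divides by cycle duration and
frame quantisation at 300 Hz would otherwise bias it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as sp_signal

from .trajio import DIGITS

#: Default minimum inter-peak period (s): half the ~0.4 s plateau cycle.
DEFAULT_MIN_PERIOD = 0.2

#: Default peak prominence as a fraction of the signal standard deviation.
DEFAULT_MIN_PROMINENCE_FRAC = 0.25


class DegenerateTrajectoryError(ValueError):
    """The trajectory carries no usable extension signal (zero variance)."""


class TooFewPeaksError(ValueError):
    """Fewer than two extension peaks: no cycle can be formed."""


@dataclass
class PeakTrain:
    """Ordered times (s) of one digit's maximum extensions in one trial."""

    digit: str
    times: np.ndarray
    signal_mode: str = "axis"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass
class CycleSeries:
    """Cycle durations from one trial's thumb peak train."""

    durations: np.ndarray
    trial_median: float

    @property
    def count(self) -> int:
        return int(self.durations.size)


def extension_signal(
    trial,
    digit: str,
    mode: str = "axis",
    axis: Sequence[float] = (0.0, 1.0),
) -> np.ndarray:
    """Reduce a digit's (x, y) trajectory to the scalar extension signal.

    ``trial`` is anything exposing per-digit ``x``/``y`` dicts
    (:class:`~digitcoord.trajio.TrialRecording` or
    :class:`~digitcoord.preprocess.FilteredTrial`).
    """
    if digit not in DIGITS:
        raise ValueError(f"unknown digit {digit!r}")
    x = np.asarray(trial.x[digit], dtype=float)
    y = np.asarray(trial.y[digit], dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    if np.ptp(xc) == 0 and np.ptp(yc) == 0:
        raise DegenerateTrajectoryError(f"degenerate trajectory for digit {digit!r}")
    if mode == "axis":
        ax = np.asarray(axis, dtype=float)
        norm = np.hypot(*ax)
        if norm == 0:
            raise ValueError("extension axis must be non-zero")
        return (x * ax[0] + y * ax[1]) / norm
    if mode == "pca":
        pts = np.column_stack([xc, yc])
        cov = pts.T @ pts / max(len(pts) - 1, 1)
        w, v = np.linalg.eigh(cov)
        pc = v[:, -1]  # leading principal direction
        # deterministic sign: largest-|loading| component positive
        if pc[np.argmax(np.abs(pc))] < 0:
            pc = -pc
        return pts @ pc
    if mode == "radial":
        return np.hypot(xc, yc)
    raise ValueError(f"unknown extension mode {mode!r}; use axis, pca or radial")


def detect_peaks(
    sig: np.ndarray,
    frame_rate: float,
    min_period: float = DEFAULT_MIN_PERIOD,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    digit: str = "thumb",
    signal_mode: str = "axis",
) -> PeakTrain:
    """Detect maximum-extension peaks in a scalar signal.

    Local maxima with prominence >= ``min_prominence_frac`` times the signal
    standard deviation and spacing >= ``min_period`` seconds.  Peak times
    are refined by fitting a parabola through the three samples around each
    discrete maximum; an empty train is a valid result.
    """
    if min_period <= 0:
        raise ValueError("min_period must be positive")
    if not 0 < min_prominence_frac < 1:
        raise ValueError("min_prominence_frac must be in (0, 1)")
    sig = np.asarray(sig, dtype=float)
    sd = sig.std()
    if sd == 0:
        return PeakTrain(digit=digit, times=np.empty(0), signal_mode=signal_mode)
    distance = max(1, int(round(min_period * frame_rate)))
    idx, _ = sp_signal.find_peaks(sig, distance=distance, prominence=min_prominence_frac * sd)
    if idx.size == 0:
        return PeakTrain(digit=digit, times=np.empty(0), signal_mode=signal_mode)
    # 3-point quadratic refinement around each discrete maximum
    left = sig[idx - 1]
    mid = sig[idx]
    right = sig[idx + 1]
    denom = left - 2 * mid + right
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom != 0, 0.5 * (left - right) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    times = (idx + delta) / frame_rate
    return PeakTrain(digit=digit, times=times, signal_mode=signal_mode)


def trial_peak_trains(
    trial,
    mode: str = "axis",
    axis: Sequence[float] = (0.0, 1.0),
    min_period: float = DEFAULT_MIN_PERIOD,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
) -> Dict[str, PeakTrain]:
    """Extension-peak trains for all five digits of one (filtered) trial."""
    fr = trial.frame_rate
    return {
        d: detect_peaks(
            extension_signal(trial, d, mode=mode, axis=axis),
            fr,
            min_period=min_period,
            min_prominence_frac=min_prominence_frac,
            digit=d,
            signal_mode=mode,
        )
        for d in DIGITS
    }


def cycle_times(thumb_peaks: PeakTrain) -> CycleSeries:
    """Cycle durations = successive thumb peak differences; median per trial.

    Raises :class:`TooFewPeaksError` below two peaks — the caller logs the
    exclusion rather than inventing a value.
    """
    if thumb_peaks.n < 2:
        raise TooFewPeaksError(
            f"{thumb_peaks.n} peak(s) for digit {thumb_peaks.digit!r}: need >= 2"
        )
    durations = np.diff(thumb_peaks.times)
    return CycleSeries(durations=durations, trial_median=float(np.median(durations)))


def block_cycle_time(trial_medians: Iterable[float]) -> float:
    """Per-block cycle time: median of the block's per-trial medians."""
    vals = np.asarray(list(trial_medians), dtype=float)
    if vals.size == 0:
        raise ValueError("no trial medians in block")
    return float(np.median(vals))


def day_cycle_time(block_values: Mapping[int, float], n_blocks: int = 5) -> tuple[float, bool]:
    """Per-day cycle time: mean of the (nominally five) block values.

    Returns ``(value, complete)``; with blocks missing, the mean is over
    the available blocks and ``complete`` is False so callers can warn.
    """
    vals = np.asarray(list(block_values.values()), dtype=float)
    if vals.size == 0:
        raise ValueError("no block values for day")
    return float(vals.mean()), len(block_values) == n_blocks
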