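"""Protocol-complete synthetic datasets with known kinematic ground truth.

The raw video-derived trajectories behind the five-week ball-rotation
protocol are not publicly archived, so every pipeline stage is exercised
against a generator whose ground truth is known exactly.  The generator
emulates the measurement protocol — participants x measurement days x
5 blocks x 12 trials (one reproduction trial, ten ball-rotation trials,
one reproduction trial), 8-s trials sampled at 300 Hz — and the two
learning curves the analysis is designed to resolve:

* **performance**: the true cycle time decays exponentially with cumulative
  practice *blocks*, ``T = T_inf + (T0 - T_inf) * exp(-k_perf * u)``, from
  about 1 s toward a ~0.4 s plateau, so it already improves across the five
  blocks of day 1;
* **recognition**: the reproduction task's phase-pattern error decays with
  elapsed *days* only, ``delta = delta_inf + (delta0 - delta_inf) *
  exp(-k_rec * (day - 1))``, so it is constant within day 1 — the
  dissociation between skill acquisition and access to it is built into the
  truth model and must be recovered, not assumed, by the pipeline.

Each digit d follows a quasi-periodic 2-D path: the extension (y) axis
carries ``A_d * sin(2*pi*(t/T + phi_d))`` and the orthogonal (x) axis a
quarter-lagged component ``orth_ratio * A_d * cos(...)`` so that the
trajectory is a flat ellipse and principal-axis extension extraction is
non-degenerate; white Gaussian tracker noise is added to both axes.
Reproduction trials run slower (``rep_slowdown`` times the concurrent BRT
cycle time) and perturb each digit's phase offset with an i.i.d. wrapped
normal draw whose scale is calibrated so that the *expected circular
distance between the perturbed and true pair phases equals delta* — the
coordination-difference estimator's target is therefore known analytically.

Identical seed and config give a bit-identical dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .trajio import (
    DIGITS,
    PAIRS,
    TrialMeta,
    TrialRecording,
    pair_label,
    write_manifest,
    write_tracker_csv,
)


@dataclass(frozen=True)
class CycleTimeModel:
    """Exponential practice curve of the true cycle time (seconds)."""

    t0: float = 1.0  # naive cycle time, ~1 s on first exposure
    t_inf: float = 0.4  # plateau, ~400 ms
    k_perf: float = 0.06  # decay per practice block


@dataclass(frozen=True)
class RecognitionModel:
    """Exponential day-level decay of the reproduction phase error."""

    delta0: float = 0.12  # initial mean circular pair-phase error
    delta_inf: float = 0.04  # residual error after extended practice
    k_rec: float = 0.15  # decay per elapsed day


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic experiment.

    The protocol constants (five blocks of ten ball-rotation and two
    reproduction trials on each of five measurement days, 8-s trials at
    300 Hz, twelve participants) mirror the measurement schedule; the
    waveform and noise parameters are illustrative defaults chosen at the
    scale of fingertip tracking, not estimates fit to any dataset.
    """

    n_participants: int = 12
    days: Sequence[int] = (1, 8, 15, 22, 29)
    blocks_per_day: int = 5
    brt_trials_per_block: int = 10
    rep_trials_per_block: int = 2  # one before, one after the BRT trials
    frame_rate: float = 300.0
    trial_duration: float = 8.0
    #: per-digit base phase offsets in cycle fractions (thumb fixed at 0)
    digit_phase_offsets: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8)
    #: per-digit extension amplitudes, arbitrary units
    amplitudes: Sequence[float] = (1.0, 1.1, 1.15, 1.0, 0.85)
    #: orthogonal (quarter-lagged) component as a fraction of amplitude
    orth_ratio: float = 0.3
    #: tracker noise SD as a fraction of each digit's amplitude
    noise_sd: float = 0.05
    cycle_time_model: CycleTimeModel = field(default_factory=CycleTimeModel)
    recognition_model: RecognitionModel = field(default_factory=RecognitionModel)
    rep_slowdown: float = 1.3  # reproduction runs ~30% slower than BRT
    #: home practice between measurement days, in block-equivalents per day
    home_blocks_per_day: float = 5.0
    #: inter-participant SD of the naive cycle time (s)
    t0_sd: float = 0.08
    #: inter-participant SD of the initial recognition error
    delta0_sd: float = 0.03
    #: lognormal sigma of trial-to-trial cycle-time jitter
    trial_jitter_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.cycle_time_model
        r = self.recognition_model
        if not m.t_inf < m.t0:
            raise ValueError("cycle-time model requires t_inf < t0")
        if not (0 <= r.delta_inf <= r.delta0 <= 0.5):
            raise ValueError("recognition deltas must satisfy 0 <= delta_inf <= delta0 <= 0.5")
        if self.rep_slowdown < 1:
            raise ValueError("rep_slowdown must be >= 1")
        if len(self.digit_phase_offsets) != 5 or self.digit_phase_offsets[0] != 0:
            raise ValueError("digit_phase_offsets: 5 values with the thumb fixed at 0")
        if len(self.amplitudes) != 5:
            raise ValueError("amplitudes: one per digit")


# ---------------------------------------------------------------------------
# Wrapped-normal calibration: digit-phase jitter scale from the target
# expected circular pair distance
# ---------------------------------------------------------------------------


def expected_circular_abs(scale: float) -> float:
    """E[min(|X mod 1|, 1 - |X mod 1|)] for X ~ Normal(0, scale^2).

    The mean circular distance from zero of a wrapped-normal phase
    perturbation; increases from 0 (scale 0) to 0.25 (uniform limit).
    Computed in closed form: the distance to the nearest integer is
    piecewise linear with kinks at half-integers, so each piece integrates
    to normal-density and normal-CDF terms.
    """
    if scale <= 0:
        return 0.0
    if scale >= 3.0:
        # wrapped normal is uniform to far below machine precision here
        return 0.25
    from scipy.stats import norm

    s = float(scale)
    # |k| = 0 piece: 2 * integral_0^{1/2} x phi_s(x) dx
    total = s * np.sqrt(2 / np.pi) * (1.0 - np.exp(-1.0 / (8 * s**2)))
    k = np.arange(1, int(np.ceil(8 * s)) + 3, dtype=float)
    phi = lambda x: norm.pdf(x, scale=s)  # noqa: E731
    Phi = lambda x: norm.cdf(x, scale=s)  # noqa: E731
    terms = s**2 * (2 * phi(k) - phi(k + 0.5) - phi(k - 0.5)) + k * (
        2 * Phi(k) - Phi(k + 0.5) - Phi(k - 0.5)
    )
    return float(total + 2 * np.sum(terms))


@lru_cache(maxsize=256)
def digit_jitter_sigma(delta: float) -> float:
    """Per-digit phase-jitter SD whose induced pair error equals *delta*.

    With i.i.d. per-digit perturbations of SD sigma, a pair's phase error is
    Normal(0, 2 sigma^2) wrapped onto the circle; this inverts
    ``expected_circular_abs`` so that the expected circular pair distance is
    exactly *delta*.  Feasible for delta < 0.25 (the i.i.d. ceiling).
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if delta == 0:
        return 0.0
    if delta >= 0.245:
        raise ValueError(
            f"delta={delta} not realisable by i.i.d. digit perturbations "
            "(expected pair distance saturates at 0.25)"
        )
    pair_scale = brentq(lambda s: expected_circular_abs(s) - delta, 1e-9, 50.0, xtol=1e-10)
    return float(pair_scale / np.sqrt(2.0))


# ---------------------------------------------------------------------------
# Truth model
# ---------------------------------------------------------------------------


def practice_units(config: SimulationConfig, day: int, block: int) -> float:
    """Cumulative practice in block-equivalents at (day, block)."""
    return (day - 1) * config.home_blocks_per_day + (block - 1)


def true_cycle_time(config: SimulationConfig, t0_p: float, day: int, block: int) -> float:
    m = config.cycle_time_model
    u = practice_units(config, day, block)
    return m.t_inf + (t0_p - m.t_inf) * float(np.exp(-m.k_perf * u))


def true_delta(config: SimulationConfig, delta0_p: float, day: int) -> float:
    r = config.recognition_model
    return r.delta_inf + (delta0_p - r.delta_inf) * float(np.exp(-r.k_rec * (day - 1)))


def pair_phase_truth(config: SimulationConfig) -> Dict[str, float]:
    """True pair relative phases implied by the digit offsets.

    With the lower-numbered digit f as reference, a digit with a larger
    base offset peaks earlier, so the recovered phase is
    ``(phi_f - phi_h) mod 1``.
    """
    offs = dict(zip(DIGITS, config.digit_phase_offsets))
    return {pair_label(f, h): (offs[f] - offs[h]) % 1.0 for f, h in PAIRS}


# ---------------------------------------------------------------------------
# Trial and session synthesis
# ---------------------------------------------------------------------------


def simulate_trial(
    config: SimulationConfig,
    meta: TrialMeta,
    cycle_time: float,
    phase_offsets: Sequence[float],
    rng: np.random.Generator,
) -> TrialRecording:
    """Synthesize one trial's five-digit trajectories.

    Digit d traces ``y = A_d sin(2 pi (t / cycle_time + phi_d))`` on the
    extension axis with a quarter-lagged orthogonal x component, plus
    i.i.d. Gaussian tracker noise on both axes; confidence is 1 everywhere.
    """
    n = int(round(config.frame_rate * config.trial_duration))
    t = np.arange(n) / config.frame_rate
    x: Dict[str, np.ndarray] = {}
    y: Dict[str, np.ndarray] = {}
    conf: Dict[str, np.ndarray] = {}
    for i, d in enumerate(DIGITS):
        amp = config.amplitudes[i]
        theta = 2 * np.pi * (t / cycle_time + phase_offsets[i])
        noise = rng.normal(0.0, config.noise_sd * amp, size=(2, n))
        # fixed per-digit centre keeps digits spatially distinct, as markers are
        y[d] = 100.0 + amp * np.sin(theta) + noise[0]
        x[d] = 40.0 * i + config.orth_ratio * amp * np.cos(theta) + noise[1]
        conf[d] = np.ones(n)
    return TrialRecording(
        participant_id=meta.participant_id,
        day=meta.day,
        block=meta.block,
        trial_index=meta.trial_index,
        task=meta.task,
        frame_rate=config.frame_rate,
        duration=config.trial_duration,
        x=x,
        y=y,
        confidence=conf,
    )


@dataclass
class SimulatedSession:
    """An in-memory synthetic dataset plus its generating ground truth."""

    config: SimulationConfig
    trials: List[TrialRecording]
    truth_trials: pd.DataFrame  # one row per trial: true cycle time, delta target
    truth_pairs: pd.DataFrame  # true pair phase offsets of the base pattern

    def write(self, outdir) -> Path:
        """Write tracker CSVs, a manifest, and the ground-truth tables.

        Returns the manifest path.  File names encode the trial context,
        e.g. ``P03_day08_b2_t11_BRT.csv``.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        entries = []
        for trial in self.trials:
            name = (
                f"{trial.participant_id}_day{trial.day:02d}_b{trial.block}"
                f"_t{trial.trial_index:02d}_{trial.task}.csv"
            )
            write_tracker_csv(trial, outdir / name)
            entries.append(
                dict(
                    path=name,
                    participant_id=trial.participant_id,
                    day=trial.day,
                    block=trial.block,
                    trial_index=trial.trial_index,
                    task=trial.task,
                    frame_rate=trial.frame_rate,
                    duration=trial.duration,
                )
            )
        manifest = outdir / "manifest.csv"
        write_manifest(entries, manifest)
        self.truth_trials.to_csv(outdir / "ground_truth_trials.csv", index=False)
        self.truth_pairs.to_csv(outdir / "ground_truth_pairs.csv", index=False)
        return manifest


def simulate_session(config: SimulationConfig | None = None) -> SimulatedSession:
    """Generate the full synthetic protocol for one cohort.

    Every (participant, day, block) yields twelve trials in protocol order:
    REP, ten BRT, REP.  Per-participant naive cycle time and initial
    recognition error are drawn from a shared latent skill factor, so
    initially faster participants also reproduce more accurately — the
    covariance structure the day-1 correlation analyses look for.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    m = config.cycle_time_model

    trials: List[TrialRecording] = []
    truth_rows = []
    offsets = np.asarray(config.digit_phase_offsets, dtype=float)

    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        skill = rng.standard_normal()
        t0_p = max(m.t_inf + 0.05, m.t0 + config.t0_sd * skill)
        r = config.recognition_model
        delta0_p = float(np.clip(r.delta0 + config.delta0_sd * skill, r.delta_inf, 0.24))
        for day in config.days:
            delta_day = true_delta(config, delta0_p, day)
            sigma_day = digit_jitter_sigma(round(delta_day, 6))
            for block in range(1, config.blocks_per_day + 1):
                t_block = true_cycle_time(config, t0_p, day, block)
                task_order = (
                    ["REP"]
                    + ["BRT"] * config.brt_trials_per_block
                    + ["REP"] * (config.rep_trials_per_block - 1)
                )
                for trial_index, task in enumerate(task_order, start=1):
                    jitter = float(np.exp(rng.normal(0.0, config.trial_jitter_sd)))
                    if task == "BRT":
                        t_trial = t_block * jitter
                        phase = offsets
                        eps = np.zeros(5)
                    else:
                        t_trial = t_block * config.rep_slowdown * jitter
                        eps = rng.normal(0.0, sigma_day, size=5) if sigma_day > 0 else np.zeros(5)
                        phase = offsets + eps
                    meta = TrialMeta(
                        participant_id=pid,
                        day=day,
                        block=block,
                        trial_index=trial_index,
                        task=task,
                        frame_rate=config.frame_rate,
                        duration=config.trial_duration,
                    )
                    trials.append(simulate_trial(config, meta, t_trial, phase, rng))
                    truth_rows.append(
                        dict(
                            participant_id=pid,
                            day=day,
                            block=block,
                            trial_index=trial_index,
                            task=task,
                            true_cycle_time=t_trial,
                            block_cycle_time=t_block
                            * (config.rep_slowdown if task == "REP" else 1.0),
                            delta_target=delta_day if task == "REP" else 0.0,
                            **{f"eps_{d}": e for d, e in zip(DIGITS, eps)},
                        )
                    )

    truth_trials = pd.DataFrame(truth_rows)
    truth_pairs = pd.DataFrame(
        [dict(pair=k, true_phase=v) for k, v in pair_phase_truth(config).items()]
    )
    return SimulatedSession(
        config=config, trials=trials, truth_trials=truth_trials, truth_pairs=truth_pairs
    )
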