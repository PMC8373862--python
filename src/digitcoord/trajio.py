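"""Trajectory file I/O and the tidy result-table data model.

This module defines the on-disk contract for everything downstream:

* :class:`TrialRecording` — one fixed-duration trial of five fingertip
  trajectories (x, y, tracker confidence per frame), plus acquisition
  metadata (participant, day, block, trial index, task).
* the *tracker CSV* dialect — the three-header-row table
  (``scorer`` / ``bodyparts`` / ``coords``) emitted by markerless pose
  estimation toolboxes, with per-point ``likelihood`` — and a flat tidy
  dialect (one row per frame, ``<digit>_x / <digit>_y / <digit>_conf``
  columns). :func:`read_tracker_csv` sniffs which one it is given.
* the *session table* — the tidy long table of per-block outcome measures
  (cycle times for both tasks, the mean coordination difference and its
  ten per-pair components) written by the analysis pipeline.

No filtering, resampling or unit conversion happens here: spatial units are
arbitrary (pixels, typically) and every downstream quantity — peak times,
relative phases — is unit-free.  Frame ``i`` carries timestamp
``i / frame_rate`` seconds, 0-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical digit labels, thumb (digit 1) through little finger (digit 5).
DIGITS: tuple[str, ...] = ("thumb", "index", "middle", "ring", "little")

#: 1-based digit numbers used in pair column names (``d1`` = thumb).
DIGIT_NUMBER: dict[str, int] = {d: i + 1 for i, d in enumerate(DIGITS)}

#: The 10 unordered digit pairs, lower-numbered digit first.
PAIRS: tuple[tuple[str, str], ...] = tuple(
    (DIGITS[i], DIGITS[j]) for i in range(5) for j in range(i + 1, 5)
)

#: Recognised task labels.
TASKS = ("BRT", "REP")


def pair_label(f: str, h: str) -> str:
    """Column label ``d<i>_d<j>`` for the unordered pair of digits *f*, *h*."""
    a, b = sorted((DIGIT_NUMBER[f], DIGIT_NUMBER[h]))
    return f"d{a}_d{b}"


#: Pair columns of the session table, in canonical order.
PAIR_COLUMNS: tuple[str, ...] = tuple(pair_label(f, h) for f, h in PAIRS)


class TrackerFormatError(ValueError):
    """A trajectory file violates the expected tracker-CSV structure."""


@dataclass
class TrialRecording:
    """Fingertip trajectories of the five digits for one recorded trial.

    Parameters
    ----------
    participant_id
        Participant identifier.
    day
        Calendar day of the protocol (measurement days are 1, 8, 15, 22, 29
        in the five-week schedule; any positive integer is accepted).
    block
        Experimental block within the day, 1–5.
    trial_index
        Trial position within the block, 1–12.
    task
        ``"BRT"`` (ball rotation) or ``"REP"`` (reproduction without balls).
    x, y
        Per-digit position series in arbitrary spatial units, one entry per
        canonical digit label, each of length ``round(frame_rate * duration)``.
    confidence
        Per-digit, per-frame tracker confidence in [0, 1].
    frame_rate
        Acquisition rate in Hz (default 300).
    duration
        Trial duration in seconds (default 8).
    """

    participant_id: str
    day: int
    block: int
    trial_index: int
    task: str
    x: Dict[str, np.ndarray]
    y: Dict[str, np.ndarray]
    confidence: Dict[str, np.ndarray]
    frame_rate: float = 300.0
    duration: float = 8.0
    digits: tuple[str, ...] = DIGITS

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if tuple(self.digits) != DIGITS:
            raise ValueError(f"digits must be exactly {DIGITS}")
        n = self.n_frames
        for name, series in (("x", self.x), ("y", self.y), ("confidence", self.confidence)):
            missing = [d for d in DIGITS if d not in series]
            if missing:
                raise TrackerFormatError(f"missing digit {missing[0]!r} in {name} series")
            for d in DIGITS:
                arr = np.asarray(series[d], dtype=float)
                series[d] = arr
                if arr.ndim != 1 or arr.shape[0] != n:
                    raise ValueError(
                        f"{name} series for {d!r} has length {arr.shape}, "
                        f"expected {n} = round(frame_rate * duration)"
                    )
        for d in DIGITS:
            c = self.confidence[d]
            finite = c[np.isfinite(c)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"confidence for {d!r} outside [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds, frame i at i / frame_rate."""
        return np.arange(self.n_frames) / self.frame_rate

    def copy_with(self, **arrays) -> "TrialRecording":
        """Return a copy with some of x / y / confidence replaced."""
        kwargs = dataclasses.asdict(self)
        # asdict deep-copies dict values but not ndarray contents; rebuild cleanly
        kwargs.update(
            x={d: np.array(self.x[d]) for d in DIGITS},
            y={d: np.array(self.y[d]) for d in DIGITS},
            confidence={d: np.array(self.confidence[d]) for d in DIGITS},
        )
        kwargs.update(arrays)
        kwargs["digits"] = tuple(kwargs["digits"])
        return TrialRecording(**kwargs)


@dataclass
class TrialMeta:
    """Acquisition metadata for one trial, as stored in a dataset manifest."""

    participant_id: str
    day: int
    block: int
    trial_index: int
    task: str
    frame_rate: float = 300.0
    duration: float = 8.0


# ---------------------------------------------------------------------------
# Tracker CSV dialects
# ---------------------------------------------------------------------------

_COORD_LABELS = {"x", "y", "likelihood"}


def _sniff_dialect(path: Path) -> str:
    with open(path, "r") as fh:
        first = fh.readline()
    head = first.split(",")[0].strip().lower()
    return "tracker" if head == "scorer" else "flat"


def read_tracker_csv(path, metadata: TrialMeta) -> TrialRecording:
    """Read one trial's trajectories from a tracker CSV.

    Accepts either the three-header-row tracker dialect
    (``scorer`` / ``bodyparts`` / ``coords`` with ``x, y, likelihood`` per
    body part) or the flat tidy dialect (``<digit>_x`` etc.).  Series are
    returned in file order; confidence is taken from the ``likelihood``
    (or ``_conf``) column; no filtering is applied.

    Raises
    ------
    TrackerFormatError
        If a digit column is missing, a coords label is unknown, or rows
        are ragged / contain non-numeric cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _sniff_dialect(path)
    if dialect == "tracker":
        try:
            df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        except pd.errors.ParserError as exc:  # ragged rows
            raise TrackerFormatError(f"ragged or malformed rows in {path}: {exc}") from exc
        bodyparts = list(dict.fromkeys(c[1] for c in df.columns))
        coords_labels = {c[2] for c in df.columns}
        unknown = coords_labels - _COORD_LABELS
        if unknown:
            raise TrackerFormatError(
                f"unknown coords label(s) {sorted(unknown)} in {path}; "
                f"expected {sorted(_COORD_LABELS)}"
            )
        for d in DIGITS:
            if d not in bodyparts:
                raise TrackerFormatError(f"missing digit {d!r} in {path}")
        x, y, conf = {}, {}, {}
        scorer = df.columns[0][0]
        for d in DIGITS:
            for coord, store in (("x", x), ("y", y), ("likelihood", conf)):
                col = (scorer, d, coord)
                if col not in df.columns:
                    raise TrackerFormatError(f"missing {coord!r} column for digit {d!r} in {path}")
                vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
                store[d] = vals
        bad = next((d for d in DIGITS if np.isnan(x[d]).any() or np.isnan(y[d]).any()), None)
        if bad is not None:
            rows = np.flatnonzero(np.isnan(x[bad]) | np.isnan(y[bad]))
            raise TrackerFormatError(
                f"ragged or non-numeric rows in {path} (digit {bad!r}, first bad row {rows[0]})"
            )
    else:
        df = pd.read_csv(path)
        x, y, conf = {}, {}, {}
        for d in DIGITS:
            for suffix, store in (("_x", x), ("_y", y), ("_conf", conf)):
                col = d + suffix
                if col not in df.columns:
                    raise TrackerFormatError(f"missing digit {d!r} column {col!r} in {path}")
                store[d] = df[col].to_numpy(dtype=float)
    return TrialRecording(
        participant_id=metadata.participant_id,
        day=metadata.day,
        block=metadata.block,
        trial_index=metadata.trial_index,
        task=metadata.task,
        frame_rate=metadata.frame_rate,
        duration=metadata.duration,
        x=x,
        y=y,
        confidence=conf,
    )


def write_tracker_csv(trial: TrialRecording, path, scorer: str = "digitcoord") -> None:
    """Write a trial in the three-header-row tracker dialect.

    Round-trips through :func:`read_tracker_csv` to 6 decimals.
    """
    path = Path(path)
    columns = pd.MultiIndex.from_tuples(
        [(scorer, d, c) for d in DIGITS for c in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    cols = []
    for d in DIGITS:
        cols.extend([trial.x[d], trial.y[d], trial.confidence[d]])
    data = np.column_stack(cols)
    df = pd.DataFrame(data, columns=columns)
    df.index.name = None
    df.to_csv(path, float_format="%.6f", index=True, index_label="")


# ---------------------------------------------------------------------------
# Session table
# ---------------------------------------------------------------------------

#: Key columns identifying one block of one participant's day.
KEY_COLUMNS = ("participant_id", "day", "block")

#: Full session-table column order.
SESSION_COLUMNS: tuple[str, ...] = KEY_COLUMNS + (
    "cycle_time_brt",
    "cycle_time_rep",
    "coord_diff",
) + PAIR_COLUMNS


def validate_session_table(table: pd.DataFrame, atol: float = 1e-6) -> None:
    """Check session-table invariants; raise ``ValueError`` on violation.

    One row per (participant, day, block); phase-difference columns in
    [0, 0.5]; ``coord_diff`` equal to the mean of the ten pair columns
    within *atol* (rows with missing pairs are exempt from the mean check).
    """
    missing = [c for c in SESSION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"session table missing columns: {missing}")
    if table.duplicated(subset=list(KEY_COLUMNS)).any():
        raise ValueError("session table has duplicate (participant_id, day, block) keys")
    phase_cols = ("coord_diff",) + PAIR_COLUMNS
    for c in phase_cols:
        vals = table[c].dropna()
        if len(vals) and ((vals < -atol).any() or (vals > 0.5 + atol).any()):
            raise ValueError(f"column {c!r} outside [0, 0.5]")
    pair_block = table[list(PAIR_COLUMNS)]
    complete = pair_block.notna().all(axis=1) & table["coord_diff"].notna()
    if complete.any():
        resid = (pair_block[complete].mean(axis=1) - table.loc[complete, "coord_diff"]).abs()
        if (resid > max(atol, 1e-6)).any():
            raise ValueError("coord_diff does not equal the mean of the 10 pair columns")


def write_session_table(table: pd.DataFrame, path) -> None:
    """Write a validated session table as tidy CSV in canonical column order."""
    validate_session_table(table)
    table = table.loc[:, list(SESSION_COLUMNS)]
    table.to_csv(path, index=False, float_format="%.9f")


def read_session_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_session_table(table)
    return table


def empty_session_table() -> pd.DataFrame:
    """A session table with the canonical columns and no rows."""
    return pd.DataFrame({c: pd.Series(dtype=float) for c in SESSION_COLUMNS}).astype(
        {"participant_id": object, "day": int, "block": int}
    )


# ---------------------------------------------------------------------------
# Dataset manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = (
    "path",
    "participant_id",
    "day",
    "block",
    "trial_index",
    "task",
    "frame_rate",
    "duration",
)


def write_manifest(entries: Iterable[Mapping], path) -> None:
    """Write a dataset manifest (CSV mapping file paths to trial metadata)."""
    df = pd.DataFrame(list(entries))
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest entries missing fields: {missing}")
    df.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest at {path} missing columns: {missing}")
    return df


def load_dataset(manifest_path) -> Iterable[TrialRecording]:
    """Yield TrialRecordings for every entry of a dataset manifest.

    Paths in the manifest are resolved relative to the manifest location.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    root = manifest_path.parent
    for row in df.itertuples(index=False):
        meta = TrialMeta(
            participant_id=str(row.participant_id),
            day=int(row.day),
            block=int(row.block),
            trial_index=int(row.trial_index),
            task=str(row.task),
            frame_rate=float(row.frame_rate),
            duration=float(row.duration),
        )
        p = Path(row.path)
        if not p.is_absolute():
            p = root / p
        yield read_tracker_csv(p, meta)
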