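"""Plain-text table formats binding the pipeline stages together.

Event tables and spike tables are comma-separated text with a header row,
chosen over binary ephys containers for inspectability and lossless
round-tripping.  Readers validate the per-trial invariants (outcome/
timestamp consistency, monotone times, sorted spikes) and reject bad rows
with row-numbered messages.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Cohort, SessionEvents, SpikeTrain, OUTCOMES, TRIAL_COLUMNS

__all__ = [
    "ValidationError",
    "read_events", "write_events",
    "read_spikes", "write_spikes",
    "write_manifest", "read_manifest",
    "file_digest",
]

EVENT_COLUMNS = ["subject", "sex", "treatment", "session_id"] + TRIAL_COLUMNS
SPIKE_COLUMNS = ["unit_id", "subject", "session_id", "sex", "treatment", "spike_time_s"]
_FLOAT_FMT = "%.4f"


class ValidationError(ValueError):
    """A table violated a format invariant; the message carries the row."""


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_events(sessions: list[SessionEvents], path: str | Path) -> None:
    """Write one or more sessions to a single event-table file."""
    frames = []
    for s in sessions:
        t = s.trials.copy()
        t.insert(0, "subject", s.subject)
        t.insert(1, "sex", s.sex)
        t.insert(2, "treatment", s.treatment)
        t.insert(3, "session_id", s.session_id)
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)[EVENT_COLUMNS]
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _check_row(row, rownum: int) -> None:
    if row.outcome not in OUTCOMES:
        raise ValidationError(f"row {rownum}: unknown outcome {row.outcome!r}")
    has_cue = np.isfinite(row.t_cue_s)
    has_press = np.isfinite(row.t_press_s)
    has_exit = np.isfinite(row.t_well_exit_s)
    if (row.outcome == "premature") == has_cue:
        raise ValidationError(
            f"row {rownum}: outcome {row.outcome!r} inconsistent with cue timestamp")
    if row.outcome == "omission" and (has_press or not has_exit):
        raise ValidationError(
            f"row {rownum}: omission must have a well exit and no press")
    if row.outcome in ("correct", "incorrect") and not has_press:
        raise ValidationError(f"row {rownum}: completed trial missing press timestamp")
    seq = [row.t_init_s]
    if has_cue:
        seq.append(row.t_cue_s)
    if has_exit:
        seq.append(row.t_well_exit_s)
    if has_press:
        seq.append(row.t_press_s)
    if any(b < a for a, b in zip(seq, seq[1:])):
        raise ValidationError(f"row {rownum}: timestamps not monotone")


def read_events(path: str | Path, session_duration: float | None = None,
                response_window: float = 5.0, iti_correct: float = 5.0,
                iti_error: float = 10.0) -> list[SessionEvents]:
    """Parse an event-table file into per-session objects.

    The file may hold several sessions; one :class:`SessionEvents` is
    returned per (subject, session_id).  ``session_duration`` defaults to the
    observed event span rounded up.
    """
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"missing column(s): {sorted(missing)}")
    for rownum, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        _check_row(row, rownum)
    sessions = []
    for (subject, session_id), g in df.groupby(["subject", "session_id"], sort=True):
        meta = g[["sex", "treatment"]].drop_duplicates()
        if len(meta) != 1:
            raise ValidationError(
                f"session ({subject}, {session_id}): inconsistent sex/treatment metadata")
        trials = g[TRIAL_COLUMNS].reset_index(drop=True)
        span = float(np.nanmax(trials[["t_init_s", "t_well_exit_s", "t_press_s"]]
                               .to_numpy(dtype=float)))
        sessions.append(SessionEvents(
            subject=str(subject), sex=str(meta.iloc[0, 0]),
            treatment=str(meta.iloc[0, 1]), session_id=str(session_id),
            trials=trials,
            session_duration=session_duration or float(np.ceil(span + iti_error)),
            response_window=response_window, iti_correct=iti_correct,
            iti_error=iti_error))
    return sessions


def write_spikes(trains: list[SpikeTrain], path: str | Path) -> None:
    """Write spike trains as one row per spike, sorted within each unit."""
    frames = []
    for tr in trains:
        frames.append(pd.DataFrame({
            "unit_id": tr.unit_id, "subject": tr.subject, "session_id": tr.session_id,
            "sex": tr.sex, "treatment": tr.treatment, "spike_time_s": tr.times}))
    out = pd.concat(frames, ignore_index=True)[SPIKE_COLUMNS]
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spikes(path: str | Path, t_stop: float | None = None,
                unit_order: list[str] | None = None) -> list[SpikeTrain]:
    """Parse a spike-table file; unsorted or negative spike times are rejected.

    Units that emitted zero spikes are only recoverable through
    ``unit_order`` (a spike file has no row to represent them); when given,
    it also fixes the output ordering.
    """
    df = pd.read_csv(path)
    missing = set(SPIKE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"missing column(s): {sorted(missing)}")
    trains = {}
    for unit_id, g in df.groupby("unit_id", sort=False):
        times = g["spike_time_s"].to_numpy(dtype=float)
        if times.size and (np.any(np.diff(times) < 0) or times[0] < 0):
            raise ValidationError(
                f"unit {unit_id}: spike times must be nonnegative and nondecreasing")
        meta = g[["subject", "session_id", "sex", "treatment"]].drop_duplicates()
        if len(meta) != 1:
            raise ValidationError(f"unit {unit_id}: inconsistent metadata across rows")
        stop = t_stop if t_stop is not None else float(np.ceil(times[-1])) if times.size else 0.0
        trains[str(unit_id)] = SpikeTrain(
            unit_id=str(unit_id), subject=str(meta.iloc[0, 0]),
            session_id=str(meta.iloc[0, 1]), sex=str(meta.iloc[0, 2]),
            treatment=str(meta.iloc[0, 3]), times=times, t_stop=stop)
    if unit_order is not None:
        return [trains[u] for u in unit_order if u in trains]
    return list(trains.values())


def write_manifest(cohort: Cohort, path: str | Path) -> None:
    cohort.manifest.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
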