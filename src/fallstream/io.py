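"""Readers and writers for the on-disk dataset layout and feedback logs.

Dataset tree::

    <root>/<subject>/<activity>/trial<k>/<site>_<modality>.csv

where site is ``wrist``/``hip`` and modality is ``accel``/``gyro``.  Each CSV
has the header ``timestamp_ms,x,y,z`` (UTF-8, ``.`` decimal, LF newlines).
Feedback logs are newline-delimited JSON, one event object per line.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    ACTIVITY_VOCABULARY,
    DatasetIndex,
    EmptyTrackError,
    FeedbackEvent,
    FeedbackKind,
    FeedbackSource,
    FormatError,
    Modality,
    SensorTrack,
    Site,
    Trial,
    TrackKey,
    VocabularyError,
)

__all__ = [
    "load_track_csv",
    "load_trial_csv",
    "save_trial_csv",
    "index_dataset",
    "read_feedback_log",
    "write_feedback_log",
]

logger = logging.getLogger(__name__)

_CSV_HEADER = ["timestamp_ms", "x", "y", "z"]
_TRIAL_DIR_RE = re.compile(r"^trial(\d+)$")
_TRACK_FILE_RE = re.compile(r"^(wrist|hip)_(accel|gyro)\.csv$")


def load_track_csv(path: str | Path, site: Site, modality: Modality) -> SensorTrack:
    """Load one sensor CSV, sorting by time and dropping duplicate stamps.

    Duplicate timestamps keep their first occurrence (commodity-device logs
    commonly repeat stamps); rows are then strictly increasing in time.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyTrackError(f"{path}: file is empty") from None
    if list(frame.columns) != _CSV_HEADER:
        raise FormatError(
            f"{path}: expected header {','.join(_CSV_HEADER)!r}, "
            f"got {','.join(map(str, frame.columns))!r}"
        )
    if len(frame) == 0:
        raise EmptyTrackError(f"{path}: no samples after header")
    try:
        numeric = frame.astype(np.float64)
    except (ValueError, TypeError):
        for i, row in enumerate(frame.itertuples(index=False), start=2):
            try:
                [float(v) for v in row]
            except (ValueError, TypeError):
                raise FormatError(f"{path}: non-numeric value on line {i}") from None
        raise FormatError(f"{path}: non-numeric data") from None

    ts = numeric["timestamp_ms"].to_numpy()
    vals = numeric[["x", "y", "z"]].to_numpy()
    order = np.argsort(ts, kind="stable")
    ts, vals = ts[order], vals[order]
    keep = np.concatenate([[True], np.diff(ts) > 0])  # first occurrence wins
    return SensorTrack(
        site=site,
        modality=modality,
        timestamps=np.round(ts[keep]).astype(np.int64),
        values=vals[keep],
    )


def load_trial_csv(
    paths: dict[TrackKey, str | Path],
    *,
    subject_id: str,
    activity: str,
    repetition: int = 1,
) -> Trial:
    """Assemble a Trial from per-sensor CSV files.

    The binary label is derived from the activity name; unknown activities
    raise :class:`VocabularyError` before any file is touched.
    """
    if activity not in ACTIVITY_VOCABULARY:
        raise VocabularyError(
            f"unknown activity {activity!r}; expected one of {ACTIVITY_VOCABULARY}"
        )
    if not paths:
        raise ValueError("at least one sensor file is required")
    tracks = {
        (site, modality): load_track_csv(p, site, modality)
        for (site, modality), p in paths.items()
    }
    return Trial(subject_id=subject_id, activity=activity, tracks=tracks, repetition=repetition)


def _trial_dir(out_root: Path, trial: Trial) -> Path:
    return out_root / trial.subject_id / trial.activity / f"trial{trial.repetition}"


def save_trial_csv(trial: Trial, out_root: str | Path, *, overwrite: bool = False) -> list[Path]:
    """Write one CSV per track; round-trips bit-identically through the loader.

    Values are printed with :func:`repr` precision so float round-trips are
    exact; timestamps are integers.
    """
    out_root = Path(out_root)
    tdir = _trial_dir(out_root, trial)
    if tdir.exists() and not overwrite:
        raise FileExistsError(f"{tdir} already exists (pass overwrite=True to replace)")
    tdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for (site, modality), track in sorted(trial.tracks.items()):
        path = tdir / f"{site.value}_{modality.value}.csv"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(",".join(_CSV_HEADER) + "\n")
            for t, (x, y, z) in zip(track.timestamps, track.values):
                fh.write(f"{int(t)},{float(x)!r},{float(y)!r},{float(z)!r}\n")
        written.append(path)
    return written


def index_dataset(root: str | Path) -> DatasetIndex:
    """Walk a dataset tree and load every trial it contains.

    Stray files and directories that do not match the layout are skipped.
    Ordering is deterministic: lexicographic by subject, activity, repetition.
    """
    root = Path(root)
    trials: list[Trial] = []
    if not root.exists():
        return DatasetIndex([])
    for subject_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for activity_dir in sorted(p for p in subject_dir.iterdir() if p.is_dir()):
            if activity_dir.name not in ACTIVITY_VOCABULARY:
                logger.warning("skipping unknown activity directory %s", activity_dir)
                continue
            for trial_dir in sorted(p for p in activity_dir.iterdir() if p.is_dir()):
                m = _TRIAL_DIR_RE.match(trial_dir.name)
                if m is None:
                    logger.warning("skipping stray directory %s", trial_dir)
                    continue
                paths: dict[TrackKey, Path] = {}
                for f in sorted(trial_dir.iterdir()):
                    fm = _TRACK_FILE_RE.match(f.name)
                    if fm is None:
                        logger.warning("skipping stray file %s", f)
                        continue
                    paths[(Site(fm.group(1)), Modality(fm.group(2)))] = f
                if not paths:
                    continue
                trials.append(
                    load_trial_csv(
                        paths,
                        subject_id=subject_dir.name,
                        activity=activity_dir.name,
                        repetition=int(m.group(1)),
                    )
                )
    return DatasetIndex(trials)


def write_feedback_log(events: list[FeedbackEvent], path: str | Path) -> None:
    """Serialize feedback events as newline-delimited JSON records."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for ev in events:
            rec = {
                "kind": ev.kind.value,
                "subject_id": ev.subject_id,
                "timestamp_ms": int(ev.timestamp_ms),
                "source": ev.source.value,
                "payload": ev.window_payload.tolist(),
            }
            fh.write(json.dumps(rec) + "\n")


def read_feedback_log(path: str | Path) -> list[FeedbackEvent]:
    """Read a newline-delimited feedback log, returning events time-sorted.

    Unknown kinds raise :class:`VocabularyError`; malformed lines raise
    :class:`FormatError` carrying the line number.
    """
    events: list[FeedbackEvent] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}: malformed record on line {lineno}: {exc}") from None
            try:
                kind = FeedbackKind(rec["kind"])
            except ValueError:
                raise VocabularyError(
                    f"{path}: unknown feedback kind {rec.get('kind')!r} on line {lineno}"
                ) from None
            except KeyError:
                raise FormatError(f"{path}: record on line {lineno} lacks 'kind'") from None
            try:
                events.append(
                    FeedbackEvent(
                        kind=kind,
                        window_payload=np.asarray(rec["payload"], dtype=np.float64),
                        subject_id=str(rec["subject_id"]),
                        timestamp_ms=int(rec["timestamp_ms"]),
                        source=FeedbackSource(rec.get("source", "background")),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise FormatError(f"{path}: malformed record on line {lineno}: {exc}") from None
    events.sort(key=lambda e: e.timestamp_ms)
    return events
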