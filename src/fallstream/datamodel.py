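"""Core data model for wrist/hip IMU fall-detection trials.

A *trial* is one labelled activity recording by one subject.  Each trial
bundles up to four sensor streams (wrist/hip x accelerometer/gyroscope),
each a timestamped 3-axis series.  Falls are the positive class; the eight
activities of daily living (ADLs) are the negative class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "Site",
    "Modality",
    "FALL_ACTIVITIES",
    "ADL_ACTIVITIES",
    "ACTIVITY_VOCABULARY",
    "WRIST_DOMINANT_ADLS",
    "WHOLE_BODY_ADLS",
    "activity_label",
    "SensorTrack",
    "Trial",
    "DatasetIndex",
    "FeedbackEvent",
    "FeedbackKind",
    "FeedbackSource",
    "VocabularyError",
    "FormatError",
    "EmptyTrackError",
]


class Site(str, Enum):
    WRIST = "wrist"
    HIP = "hip"


class Modality(str, Enum):
    ACCELEROMETER = "accel"
    GYROSCOPE = "gyro"


#: Five simulated fall types (label 1).
FALL_ACTIVITIES: tuple[str, ...] = ("front", "back", "left", "right", "rotational")

#: Eight activities of daily living (label 0).
ADL_ACTIVITIES: tuple[str, ...] = (
    "walk",
    "wave",
    "drink",
    "jacket",
    "sit_stand",
    "wash_hands",
    "pick_up",
    "sweep",
)

ACTIVITY_VOCABULARY: tuple[str, ...] = FALL_ACTIVITIES + ADL_ACTIVITIES

#: ADLs whose motion is concentrated at the wrist (hip stays near-quiescent).
WRIST_DOMINANT_ADLS: tuple[str, ...] = ("wave", "drink", "jacket", "wash_hands")

#: ADLs that move the whole body, producing moderate hip motion.
WHOLE_BODY_ADLS: tuple[str, ...] = ("walk", "sit_stand", "pick_up", "sweep")


class VocabularyError(ValueError):
    """An activity or feedback kind outside the known vocabulary."""


class FormatError(ValueError):
    """A malformed on-disk record (names the file and line where possible)."""


class EmptyTrackError(ValueError):
    """A sensor file with a header but no samples."""


def activity_label(activity: str) -> int:
    """Binary label for an activity name: 1 for the five fall types, 0 for ADLs.

    Raises
    ------
    VocabularyError
        If ``activity`` is not one of the 13 known activities.
    """
    if activity in FALL_ACTIVITIES:
        return 1
    if activity in ADL_ACTIVITIES:
        return 0
    raise VocabularyError(
        f"unknown activity {activity!r}; expected one of {ACTIVITY_VOCABULARY}"
    )


@dataclass
class SensorTrack:
    """One sensor stream: a timestamped 3-axis series from one site/modality.

    Accelerometer values are gravity-inclusive specific force in m/s^2;
    gyroscope values are angular rate in rad/s.  Timestamps are integer
    milliseconds, strictly increasing after loader de-duplication.
    """

    site: Site
    modality: Modality
    timestamps: np.ndarray  # (T,) int64, ms
    values: np.ndarray  # (T, 3) float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.timestamps.ndim != 1 or self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("timestamps must be (T,), values must be (T, 3)")
        if len(self.timestamps) != len(self.values):
            raise ValueError(
                f"length mismatch: {len(self.timestamps)} timestamps, "
                f"{len(self.values)} value rows"
            )
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def median_period_ms(self) -> float:
        """Empirical median sampling period (nominal is ~32 ms on the watch)."""
        if len(self) < 2:
            return float("nan")
        return float(np.median(np.diff(self.timestamps)))

    @property
    def magnitude(self) -> np.ndarray:
        """Euclidean norm per sample."""
        return np.linalg.norm(self.values, axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SensorTrack):
            return NotImplemented
        return (
            self.site == other.site
            and self.modality == other.modality
            and np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.values, other.values)
        )


TrackKey = tuple[Site, Modality]


@dataclass
class Trial:
    """One labelled activity recording bundling up to four sensor tracks."""

    subject_id: str
    activity: str
    tracks: dict[TrackKey, SensorTrack]
    repetition: int = 1
    label: int = field(init=False)

    def __post_init__(self) -> None:
        self.label = activity_label(self.activity)
        if self.repetition < 1:
            raise ValueError("repetition must be >= 1")
        if not self.tracks:
            raise ValueError("a trial needs at least one sensor track")
        for (site, modality), track in self.tracks.items():
            if (track.site, track.modality) != (site, modality):
                raise ValueError(
                    f"track stored under {(site, modality)} declares "
                    f"{(track.site, track.modality)}"
                )

    @property
    def trial_id(self) -> str:
        return f"{self.subject_id}/{self.activity}/trial{self.repetition}"

    def track(self, site: Site, modality: Modality) -> SensorTrack:
        return self.tracks[(site, modality)]


@dataclass
class DatasetIndex:
    """An ordered view over a collection of trials.

    Trials are kept sorted lexicographically by (subject, activity,
    repetition) so downstream training is deterministic.
    """

    trials: list[Trial]

    def __post_init__(self) -> None:
        self.trials = sorted(
            self.trials, key=lambda t: (t.subject_id, t.activity, t.repetition)
        )

    @property
    def subjects(self) -> list[str]:
        return sorted({t.subject_id for t in self.trials})

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.trials:
            out[t.activity] = out.get(t.activity, 0) + 1
        return out

    @property
    def n_fall_trials(self) -> int:
        return sum(1 for t in self.trials if t.label == 1)

    @property
    def n_adl_trials(self) -> int:
        return sum(1 for t in self.trials if t.label == 0)

    def __len__(self) -> int:
        return len(self.trials)

    def subset(self, subjects) -> "DatasetIndex":
        wanted = set(subjects)
        return DatasetIndex([t for t in self.trials if t.subject_id in wanted])


class FeedbackKind(str, Enum):
    TP = "TP"  # user-confirmed alarm -> fall class
    FP = "FP"  # user-rejected alarm -> ADL class
    TN = "TN"  # sampled quiet window -> ADL class
    FN = "FN"  # user-reported missed fall -> fall class


class FeedbackSource(str, Enum):
    TRIGGER_CONFIRMED = "trigger_confirmed"
    TRIGGER_REJECTED = "trigger_rejected"
    USER_REPORTED_FALL = "user_reported_fall"
    BACKGROUND = "background"


@dataclass
class FeedbackEvent:
    """One TP/FP/TN/FN-labelled window payload captured from streaming use.

    TP and FN events are treated as fall-class (label 1) for retraining;
    FP and TN events as ADL-class (label 0).
    """

    kind: FeedbackKind
    window_payload: np.ndarray  # (L, C) with L >= one window
    subject_id: str
    timestamp_ms: int
    source: FeedbackSource

    def __post_init__(self) -> None:
        self.kind = FeedbackKind(self.kind)
        self.source = FeedbackSource(self.source)
        self.window_payload = np.asarray(self.window_payload, dtype=np.float64)
        if self.window_payload.ndim != 2:
            raise ValueError("window_payload must be a 2-D (length x channels) array")

    @property
    def retrain_label(self) -> int:
        return 1 if self.kind in (FeedbackKind.TP, FeedbackKind.FN) else 0
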