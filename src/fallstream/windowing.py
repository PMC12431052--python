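"""Sliding-window segmentation and multi-sensor channel stacking.

Trials are resampled onto a single reference clock (the wrist accelerometer
by default), horizontally stacked per the selected sensor combination, then
cut into fixed-length overlapping windows.  Defaults follow the deployed
system: 128-sample windows (~4.1 s at the 32 ms watch period) sliding by 32
samples.  No filtering or normalization is applied — the classifier trains
on raw signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import Modality, Site, Trial

__all__ = [
    "CHANNEL_ORDER",
    "CHANNEL_TO_TRACK",
    "SensorCombo",
    "WindowingConfig",
    "WindowBatch",
    "ChannelMissingError",
    "InsufficientLengthError",
    "align_tracks",
    "segment",
    "label_windows",
    "window_duration_s",
    "windows_from_trial",
    "windows_from_index",
]

#: Canonical channel order: wrist accel < wrist gyro < hip accel < hip gyro.
CHANNEL_ORDER: tuple[str, ...] = ("wA", "wG", "hA", "hG")

CHANNEL_TO_TRACK: dict[str, tuple[Site, Modality]] = {
    "wA": (Site.WRIST, Modality.ACCELEROMETER),
    "wG": (Site.WRIST, Modality.GYROSCOPE),
    "hA": (Site.HIP, Modality.ACCELEROMETER),
    "hG": (Site.HIP, Modality.GYROSCOPE),
}


class ChannelMissingError(KeyError):
    """A combo channel absent from the trial."""


class InsufficientLengthError(ValueError):
    """Aligned signal shorter than one window."""


@dataclass(frozen=True)
class SensorCombo:
    """An ordered subset of {wA, wG, hA, hG}; order is always canonical, so
    the declaration order of channels never matters."""

    channels: tuple[str, ...]

    def __init__(self, channels) -> None:
        if isinstance(channels, str):
            channels = channels.split("+")
        channels = list(channels)
        unknown = [c for c in channels if c not in CHANNEL_ORDER]
        if unknown:
            raise ValueError(f"unknown channels {unknown}; valid: {CHANNEL_ORDER}")
        if not channels:
            raise ValueError("a sensor combo must name at least one channel")
        if len(set(channels)) != len(channels):
            raise ValueError(f"duplicate channels in {channels}")
        object.__setattr__(
            self, "channels", tuple(sorted(channels, key=CHANNEL_ORDER.index))
        )

    @property
    def width(self) -> int:
        """Fused per-time-step width: 3 axes per channel."""
        return 3 * len(self.channels)

    @property
    def name(self) -> str:
        return "+".join(self.channels)

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class WindowingConfig:
    window_size: int = 128
    step_size: int = 32

    def __post_init__(self) -> None:
        if not (1 <= self.step_size <= self.window_size):
            raise ValueError("need 1 <= step_size <= window_size")


@dataclass
class WindowBatch:
    """Fixed-shape windows ready for training or inference.

    ``windows`` is (N, window_size, C); ``labels`` is (N,) in {0, 1};
    ``provenance`` records (trial_id-or-source, start index) per window.
    """

    windows: np.ndarray
    labels: np.ndarray
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (N, window_size, C)")
        if len(self.windows) != len(self.labels):
            raise ValueError("windows and labels must align")
        if len(self.labels) and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def subjects(self) -> list[str]:
        return sorted({src.split("/")[0] for src, _ in self.provenance})

    @staticmethod
    def concatenate(batches: list["WindowBatch"]) -> "WindowBatch":
        batches = [b for b in batches if len(b)]
        if not batches:
            raise ValueError("nothing to concatenate")
        return WindowBatch(
            windows=np.concatenate([b.windows for b in batches]),
            labels=np.concatenate([b.labels for b in batches]),
            provenance=[p for b in batches for p in b.provenance],
        )


def align_tracks(trial: Trial, combo: SensorCombo, config: WindowingConfig) -> np.ndarray:
    """Resample the combo's tracks onto one reference grid and stack them.

    The reference clock is the wrist accelerometer when present, else the
    first present channel in canonical order.  Other channels are linearly
    interpolated per axis; rows outside the common time overlap are dropped.
    Returns a T x (3*k) float matrix in canonical channel order.
    """
    tracks = {}
    for ch in combo.channels:
        key = CHANNEL_TO_TRACK[ch]
        if key not in trial.tracks:
            raise ChannelMissingError(f"trial {trial.trial_id} lacks channel {ch}")
        tracks[ch] = trial.tracks[key]

    ref = tracks.get("wA") or tracks[combo.channels[0]]
    ref_t = ref.timestamps
    t_lo = max(tr.timestamps[0] for tr in tracks.values())
    t_hi = min(tr.timestamps[-1] for tr in tracks.values())
    keep = (ref_t >= t_lo) & (ref_t <= t_hi)
    grid = ref_t[keep]
    if len(grid) < config.window_size:
        raise InsufficientLengthError(
            f"trial {trial.trial_id}: overlap of {len(grid)} samples is shorter "
            f"than one {config.window_size}-sample window"
        )
    cols = []
    for ch in combo.channels:
        tr = tracks[ch]
        if tr is ref:
            cols.append(tr.values[keep])
        else:
            cols.append(
                np.column_stack(
                    [np.interp(grid, tr.timestamps, tr.values[:, a]) for a in range(3)]
                )
            )
    return np.concatenate(cols, axis=1)


def segment(matrix: np.ndarray, config: WindowingConfig) -> tuple[np.ndarray, np.ndarray]:
    """Cut a T x C matrix into overlapping windows.

    Windows are half-open ranges [s, s + window_size) at s = 0, step, 2*step,
    ...; a trailing remainder shorter than a window is dropped.  Returns
    (windows (N, window_size, C), start indices (N,)).
    """
    matrix = np.asarray(matrix)
    T = matrix.shape[0]
    w, s = config.window_size, config.step_size
    if T < w:
        raise InsufficientLengthError(f"signal of length {T} is shorter than one window ({w})")
    starts = np.arange(0, T - w + 1, s)
    windows = np.stack([matrix[i : i + w] for i in starts])
    return windows, starts


def label_windows(
    windows: np.ndarray, starts: np.ndarray, trial: Trial
) -> WindowBatch:
    """Every window inherits its source trial's binary label."""
    return WindowBatch(
        windows=windows,
        labels=np.full(len(windows), trial.label, dtype=np.int64),
        provenance=[(trial.trial_id, int(s)) for s in starts],
    )


def window_duration_s(config: WindowingConfig, sampling_period_ms: float) -> float:
    """Wall-clock span of one window (128 x 32 ms ~= 4.1 s)."""
    if sampling_period_ms <= 0:
        raise ValueError("sampling_period_ms must be positive")
    return config.window_size * sampling_period_ms / 1000.0


def windows_from_trial(trial: Trial, combo: SensorCombo, config: WindowingConfig) -> WindowBatch:
    """align -> segment -> label for one trial."""
    matrix = align_tracks(trial, combo, config)
    windows, starts = segment(matrix, config)
    return label_windows(windows, starts, trial)


def windows_from_index(index, combo: SensorCombo, config: WindowingConfig) -> WindowBatch:
    """Build a fused window batch over every trial in a dataset index."""
    return WindowBatch.concatenate(
        [windows_from_trial(t, combo, config) for t in index.trials]
    )
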