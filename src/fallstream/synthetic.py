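"""Seeded synthetic wrist/hip IMU generator for falls and daily activities.

The generator emulates the qualitative signal morphology of simulated-fall
datasets collected on a smartwatch (left wrist) and smartphone (right hip):

* **Falls** (front, back, left, right, rotational): a brief sub-gravity
  free-fall dip followed by a synchronized half-sine impact burst on *both*
  wrist and hip accelerometers, with peak magnitudes of roughly 15-20 m/s^2,
  then a short damped aftermath.
* **Wrist-dominant ADLs** (wave, drink, jacket, wash_hands): oscillatory
  wrist bursts whose peak magnitude overlaps the fall range — the source of
  wrist-only false alarms — while the hip stays near-quiescent (deviation
  from gravity well under 2 m/s^2).
* **Whole-body ADLs** (walk, sit_stand, pick_up, sweep): moderate motion at
  both sites (hip deviation a few m/s^2).

The signal model is gravity + parametric activity envelope + Gaussian noise.
Gyroscope tracks are scaled, phase-shifted companions of the site envelope
with independent noise.  Everything is deterministic given the config seed;
per-trial streams are derived by hashing (seed, subject, activity, rep) so
trials are reproducible in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .datamodel import (
    ACTIVITY_VOCABULARY,
    ADL_ACTIVITIES,
    FALL_ACTIVITIES,
    DatasetIndex,
    Modality,
    SensorTrack,
    Site,
    Trial,
    VocabularyError,
    WHOLE_BODY_ADLS,
    WRIST_DOMINANT_ADLS,
)
from .io import save_trial_csv

__all__ = [
    "GeneratorConfig",
    "StreamAnnotation",
    "Stream",
    "STREAM_ONLY_ACTIVITIES",
    "generate_trial",
    "generate_cohort",
    "generate_stream",
]

#: Activities permitted only in continuous streams: ambiguous movements that
#: the 13-activity trial protocol does not cover, used to provoke realistic
#: false alarms — hard heel strikes on stairs, and lying down onto a bed
#: (a sustained posture change without a hard impact).
STREAM_ONLY_ACTIVITIES: tuple[str, ...] = ("stairs", "lie_down")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic world.

    Amplitude ranges are peak accelerometer *magnitudes* (gravity-inclusive)
    in m/s^2 for impacts/oscillations, except ``hip_adl_peak_ms2`` and
    ``wrist_wholebody_peak_ms2`` which are peak deviations from gravity.
    """

    sampling_period_ms: float = 32.0
    trial_duration_s: float = 12.0
    fall_impact_peak_ms2: tuple[float, float] = (15.0, 20.0)
    wrist_adl_peak_ms2: tuple[float, float] = (15.0, 20.0)
    hip_adl_peak_ms2: tuple[float, float] = (2.0, 6.0)
    wrist_wholebody_peak_ms2: tuple[float, float] = (3.0, 8.0)
    ambiguous_hip_peak_ms2: tuple[float, float] = (12.0, 18.0)
    noise_sd: float = 0.3
    gyro_noise_sd: float = 0.05
    gravity_ms2: float = 9.81
    subject_amplitude_sd: float = 0.1
    timestamp_jitter_ms: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_period_ms <= 0:
            raise ValueError("sampling_period_ms must be positive")
        for name in (
            "fall_impact_peak_ms2",
            "wrist_adl_peak_ms2",
            "hip_adl_peak_ms2",
            "wrist_wholebody_peak_ms2",
            "ambiguous_hip_peak_ms2",
        ):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must be a non-empty non-negative range")


def _derive_rng(config: GeneratorConfig, *tokens) -> np.random.Generator:
    """Stable per-entity RNG: hash the seed with string tokens."""
    h = hashlib.sha256()
    h.update(str(config.seed).encode())
    for t in tokens:
        h.update(b"\x1f" + str(t).encode())
    return np.random.default_rng(int.from_bytes(h.digest()[:8], "big"))


@dataclass(frozen=True)
class _SubjectTraits:
    amplitude: float  # multiplicative, ~N(1, subject_amplitude_sd)
    frequency: float  # multiplicative tempo factor


def _subject_traits(config: GeneratorConfig, subject_id: str) -> _SubjectTraits:
    rng = _derive_rng(config, "subject", subject_id)
    amp = float(np.clip(rng.normal(1.0, config.subject_amplitude_sd), 0.6, 1.4))
    freq = float(np.clip(rng.normal(1.0, config.subject_amplitude_sd), 0.6, 1.4))
    return _SubjectTraits(amplitude=amp, frequency=freq)


def _pick_peak(rng, lo: float, hi: float, traits: _SubjectTraits) -> float:
    """Draw a peak target in [lo, hi], nudged by the subject factor but clipped
    so the stated amplitude range is always honoured."""
    base = rng.uniform(lo, hi)
    return float(np.clip(base * traits.amplitude, lo, hi))


def _burst_amplitude(peak_mag: float, direction: np.ndarray, g: float) -> float:
    """Envelope amplitude A so that |A*d + g*e_z| == peak_mag at the apex."""
    dz = direction[2]
    disc = g * g * dz * dz + peak_mag * peak_mag - g * g
    return float(-g * dz + np.sqrt(max(disc, 0.0)))


def _half_sine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Half-sine pulse supported on [center - width/2, center + width/2]."""
    phase = (t - center) / width + 0.5
    out = np.sin(np.pi * np.clip(phase, 0.0, 1.0))
    out[(phase <= 0) | (phase >= 1)] = 0.0
    return out


def _hann_burst(t: np.ndarray, start: float, duration: float, freq: float, phase: float = 0.0) -> np.ndarray:
    """Sinusoid at ``freq`` Hz under a Hann window on [start, start+duration]."""
    u = (t - start) / duration
    win = 0.5 - 0.5 * np.cos(2 * np.pi * np.clip(u, 0.0, 1.0))
    win[(u < 0) | (u > 1)] = 0.0
    return win * np.sin(2 * np.pi * freq * (t - start) + phase)


_FALL_DIRECTIONS = {
    "front": np.array([0.95, 0.0, 0.3]),
    "back": np.array([-0.95, 0.0, 0.3]),
    "left": np.array([0.0, -0.95, 0.3]),
    "right": np.array([0.0, 0.95, 0.3]),
    "rotational": np.array([0.65, 0.65, 0.35]),
}
for _k in _FALL_DIRECTIONS:
    _FALL_DIRECTIONS[_k] = _FALL_DIRECTIONS[_k] / np.linalg.norm(_FALL_DIRECTIONS[_k])

_EZ = np.array([0.0, 0.0, 1.0])


def _smoothstep(t: np.ndarray, start: float, duration: float) -> np.ndarray:
    """0 -> 1 cosine ramp over [start, start + duration]."""
    u = np.clip((t - start) / duration, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * u)


def _tilt_deviation(g: float, theta: np.ndarray, axis_xy: np.ndarray) -> np.ndarray:
    """Accelerometer deviation caused by tilting the sensor by ``theta``
    (radians, per-sample) about a horizontal axis: gravity leaves +z."""
    ux, uy = axis_xy / np.linalg.norm(axis_xy)
    lateral = np.array([uy, -ux, 0.0])
    return g * (
        (np.cos(theta) - 1.0)[:, None] * _EZ + np.sin(theta)[:, None] * lateral
    )


def _scale_burst_to_peak(base: np.ndarray, burst: np.ndarray, target: float) -> np.ndarray:
    """Scale ``burst`` so the peak magnitude of ``base + c*burst`` hits
    ``target`` (bisection; ``base`` includes gravity, everything noise-free)."""
    def peak(c: float) -> float:
        return float(np.linalg.norm(base + c * burst, axis=1).max())

    if peak(0.0) >= target or not np.any(burst):
        return np.zeros_like(burst)
    hi = 1.0
    while peak(hi) < target and hi < 1e6:
        hi *= 2.0
    lo = 0.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if peak(mid) < target:
            lo = mid
        else:
            hi = mid
    return hi * burst


def _fall_envelope(t, rng, config, traits, activity, t_impact=None, lie_until=None):
    """Accel deviation (wrist, hip) and gyro rates for one fall event.

    The morphology is the standard fall sequence: upright ambulation, a brief
    sub-gravity free-fall dip, a sharp synchronized impact on both sites, then
    the persistent post-impact posture change — gravity rotated off the
    vertical while the subject lies on the mattress (until ``lie_until``,
    default the end of the trial).
    """
    g = config.gravity_ms2
    d = _FALL_DIRECTIONS[activity]
    if t_impact is None:
        t_impact = rng.uniform(0.25, 0.40) * t[-1]
    if lie_until is None:
        lie_until = t[-1] + 1.0  # lying persists to the end of the recording
    width = rng.uniform(0.16, 0.24)

    wrist = np.zeros((len(t), 3))
    hip = np.zeros((len(t), 3))
    # Light pre-fall sway (the subject is standing/stepping before the fall).
    sway = np.sin(2 * np.pi * 1.6 * traits.frequency * t) * (t < t_impact - 0.3)
    wrist += 0.8 * sway[:, None] * np.array([0.6, 0.4, 0.5])
    hip += 0.6 * sway[:, None] * np.array([0.5, 0.3, 0.6])
    # Free-fall dip: gravity support drops briefly before impact.
    dip = _half_sine(t, t_impact - 0.18, 0.3)
    for dev in (wrist, hip):
        dev[:, 2] -= 0.7 * g * dip
    # Post-impact posture change: tilt ramps up over ~0.6 s and holds.
    theta_lie = np.deg2rad(rng.uniform(70.0, 100.0))
    axis = d[:2] if np.linalg.norm(d[:2]) > 1e-6 else np.array([1.0, 0.0])
    ramp = _smoothstep(t, t_impact, 0.6)
    if lie_until < t[-1]:
        ramp = ramp * (1.0 - _smoothstep(t, lie_until, 0.8))
    for dev, jig in ((wrist, rng.uniform(0.85, 1.0)), (hip, 1.0)):
        dev += _tilt_deviation(g, theta_lie * ramp * jig, axis)
    # Damped aftermath wobble on top of the new posture.
    after = _hann_burst(t, t_impact + width, 1.2, 2.5 * traits.frequency)
    wrist += 1.0 * after[:, None] * d
    hip += 0.6 * after[:, None] * d
    # Synchronized impact burst on both sites, scaled so the noise-free peak
    # magnitude equals the drawn target (independent per site).
    lo, hi = config.fall_impact_peak_ms2
    gravity = g * _EZ
    for dev, jitter in ((wrist, 0.0), (hip, rng.uniform(-0.02, 0.02))):
        peak = _pick_peak(rng, lo, hi, traits)
        burst = _half_sine(t, t_impact + jitter, width)[:, None] * d
        dev += _scale_burst_to_peak(dev + gravity, burst, peak)

    tumble = _half_sine(t, t_impact - 0.05, 0.5)
    gyro_peak = rng.uniform(4.0, 8.0) if activity == "rotational" else rng.uniform(2.0, 5.0)
    gaxis = np.array([d[1], -d[0], 0.4])
    gaxis /= np.linalg.norm(gaxis)
    wrist_gyro = gyro_peak * tumble[:, None] * gaxis
    hip_gyro = 0.8 * gyro_peak * _half_sine(t, t_impact, 0.5)[:, None] * gaxis
    return wrist, hip, wrist_gyro, hip_gyro, (t_impact - 0.3, min(lie_until, t[-1]))


def _wrist_adl_envelope(t, rng, config, traits, activity, start=None, duration=None):
    """Wrist-dominant ADL: vigorous wrist oscillation plus large transient
    wrist-orientation excursions (drinking, dressing and washing all rotate
    the watch), while the hip stays quiescent.  The wrist channel is thus
    genuinely confusable with falls; the hip is not."""
    g = config.gravity_ms2
    if duration is None:
        duration = rng.uniform(0.5, 0.75) * t[-1]
    if start is None:
        start = rng.uniform(0.1, 0.9) * (t[-1] - duration)
    freq = rng.uniform(1.5, 3.5) * traits.frequency
    phi = rng.uniform(0, 2 * np.pi)
    d = np.array([np.cos(phi), np.sin(phi), rng.uniform(-0.2, 0.2)])
    d /= np.linalg.norm(d)
    # Sustained orientation plateau: the wrist rotates and *stays* rotated for
    # most of the activity (washing, dressing, drinking hold the watch off the
    # vertical), so wrist-only windows genuinely resemble post-fall posture.
    theta_max = np.deg2rad(rng.uniform(55.0, 110.0))
    hold = rng.uniform(0.6, 0.95) * duration
    hold_start = start + rng.uniform(0.0, duration - hold)
    plateau = _smoothstep(t, hold_start, 0.7) * (1.0 - _smoothstep(t, hold_start + hold, 0.7))
    wobble = 1.0 + 0.15 * np.sin(2 * np.pi * rng.uniform(0.2, 0.5) * t + rng.uniform(0, 2 * np.pi))
    wrist = _tilt_deviation(g, theta_max * plateau * wobble, np.array([np.cos(phi), np.sin(phi)]))
    # Fast oscillation scaled so the combined noise-free peak hits the target.
    lo, hi = config.wrist_adl_peak_ms2
    peak = _pick_peak(rng, lo, hi, traits)
    burst = _hann_burst(t, start, duration, freq)[:, None] * d
    wrist += _scale_burst_to_peak(wrist + g * _EZ, burst, peak)
    hip = np.zeros((len(t), 3))
    wrist_gyro = rng.uniform(1.0, 3.0) * np.abs(_hann_burst(t, start, duration, freq))[:, None] * np.array([0.6, 0.6, 0.5])
    hip_gyro = np.zeros((len(t), 3))
    return wrist, hip, wrist_gyro, hip_gyro, (start, start + duration)


def _whole_body_envelope(t, rng, config, traits, activity, start=None, duration=None):
    """Whole-body ADL: moderate rhythmic motion at both sites."""
    g = config.gravity_ms2
    if duration is None:
        duration = rng.uniform(0.6, 0.85) * t[-1]
    if start is None:
        start = rng.uniform(0.1, 0.9) * (t[-1] - duration)
    freq = rng.uniform(0.8, 2.0) * traits.frequency
    lo, hi = config.hip_adl_peak_ms2
    hip_dev = _pick_peak(rng, lo, hi, traits)
    wlo, whi = config.wrist_wholebody_peak_ms2
    wrist_dev = _pick_peak(rng, wlo, whi, traits)
    dh = np.array([0.7, 0.2, 0.7]) / np.linalg.norm([0.7, 0.2, 0.7])
    dw = np.array([0.6, 0.6, 0.5]) / np.linalg.norm([0.6, 0.6, 0.5])
    burst_h = _hann_burst(t, start, duration, freq)
    burst_w = _hann_burst(t, start, duration, freq * 1.3, phase=0.7)
    hip = _burst_amplitude(g + hip_dev, dh, g) * burst_h[:, None] * dh
    wrist = _burst_amplitude(g + wrist_dev, dw, g) * burst_w[:, None] * dw
    wrist_gyro = rng.uniform(0.5, 1.5) * np.abs(burst_w)[:, None] * np.array([0.5, 0.5, 0.7])
    hip_gyro = rng.uniform(0.3, 1.0) * np.abs(burst_h)[:, None] * np.array([0.5, 0.5, 0.7])
    return wrist, hip, wrist_gyro, hip_gyro, (start, start + duration)


def _stairs_envelope(t, rng, config, traits, start=None, duration=None):
    """Ambiguous stream-only activity: repeated hard heel strikes whose hip
    impact magnitude overlaps the fall range (the classic false-alarm case)."""
    g = config.gravity_ms2
    if duration is None:
        duration = rng.uniform(2.0, 3.0)
    if start is None:
        start = rng.uniform(0.1, 0.9) * (t[-1] - duration)
    cadence = rng.uniform(1.6, 2.2) * traits.frequency
    n_steps = max(2, int(duration * cadence))
    d = np.array([0.5, 0.3, 0.8])
    d /= np.linalg.norm(d)
    wrist = np.zeros((len(t), 3))
    hip = np.zeros((len(t), 3))
    lo, hi = config.ambiguous_hip_peak_ms2
    for k in range(n_steps):
        c = start + (k + 0.5) * duration / n_steps
        hp = _pick_peak(rng, lo, hi, traits)
        wp = _pick_peak(rng, 0.7 * lo, 0.9 * hi, traits)
        hip += _burst_amplitude(hp, d, g) * _half_sine(t, c, 0.18)[:, None] * d
        wrist += _burst_amplitude(wp, d, g) * _half_sine(t, c + 0.02, 0.18)[:, None] * d
    sway = _hann_burst(t, start, duration, cadence)
    wrist_gyro = rng.uniform(1.0, 2.5) * np.abs(sway)[:, None] * np.array([0.5, 0.5, 0.6])
    hip_gyro = rng.uniform(0.8, 2.0) * np.abs(sway)[:, None] * np.array([0.5, 0.5, 0.6])
    return wrist, hip, wrist_gyro, hip_gyro, (start, start + duration)


def _lie_down_envelope(t, rng, config, traits, start=None, duration=None):
    """Ambiguous stream-only activity: lying down onto a bed or sofa — a
    sustained posture change at both sites with only a soft bump, the classic
    false-positive for posture-aware fall detectors."""
    g = config.gravity_ms2
    if duration is None:
        duration = rng.uniform(6.0, 8.0)
    if start is None:
        start = rng.uniform(0.1, 0.9) * (t[-1] - duration)
    theta_lie = np.deg2rad(rng.uniform(70.0, 95.0))
    phi = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.cos(phi), np.sin(phi)])
    settle = start + rng.uniform(0.8, 1.4)
    ramp = _smoothstep(t, start, settle - start) * (1.0 - _smoothstep(t, start + duration - 0.8, 0.8))
    wrist = _tilt_deviation(g, theta_lie * ramp * rng.uniform(0.85, 1.0), axis)
    hip = _tilt_deviation(g, theta_lie * ramp, axis)
    # Soft settling bump, clearly below the fall impact range.
    d = np.array([axis[0], axis[1], 0.5])
    d /= np.linalg.norm(d)
    bump_peak = rng.uniform(10.0, 13.5)
    bump = _half_sine(t, settle, 0.35)[:, None] * d
    hip += _scale_burst_to_peak(hip + g * _EZ, bump, bump_peak)
    wrist += _scale_burst_to_peak(wrist + g * _EZ, 0.8 * bump, 0.9 * bump_peak)
    turn = _half_sine(t, settle - 0.3, 0.9)
    wrist_gyro = rng.uniform(1.0, 2.0) * turn[:, None] * np.array([0.5, 0.5, 0.4])
    hip_gyro = rng.uniform(0.8, 1.6) * turn[:, None] * np.array([0.5, 0.5, 0.4])
    return wrist, hip, wrist_gyro, hip_gyro, (start, start + duration)


def _activity_envelope(activity, t, rng, config, traits, start=None, duration=None):
    if activity in FALL_ACTIVITIES:
        return _fall_envelope(t, rng, config, traits, activity, t_impact=start)
    if activity in WRIST_DOMINANT_ADLS:
        return _wrist_adl_envelope(t, rng, config, traits, activity, start, duration)
    if activity in WHOLE_BODY_ADLS:
        return _whole_body_envelope(t, rng, config, traits, activity, start, duration)
    if activity == "stairs":
        return _stairs_envelope(t, rng, config, traits, start, duration)
    if activity == "lie_down":
        return _lie_down_envelope(t, rng, config, traits, start, duration)
    raise VocabularyError(f"unknown activity {activity!r}")


def _timestamps(n: int, config: GeneratorConfig, rng) -> np.ndarray:
    ideal = np.arange(n) * config.sampling_period_ms
    if config.timestamp_jitter_ms > 0:
        ideal = ideal + rng.uniform(-config.timestamp_jitter_ms, config.timestamp_jitter_ms, n)
    ts = np.round(ideal).astype(np.int64)
    ts[0] = max(ts[0], 0)
    return ts


def generate_trial(
    activity: str,
    subject_id: str,
    config: GeneratorConfig,
    *,
    repetition: int = 1,
) -> Trial:
    """Generate one four-track trial, deterministic in (activity, subject, seed).

    Fall trials contain exactly one impact whose wrist *and* hip accelerometer
    peak magnitudes lie in ``config.fall_impact_peak_ms2`` (up to sensor
    noise); wrist-dominant ADLs keep the hip within ~noise of gravity.
    """
    if activity not in ACTIVITY_VOCABULARY:
        raise VocabularyError(
            f"unknown activity {activity!r}; expected one of {ACTIVITY_VOCABULARY}"
        )
    rng = _derive_rng(config, "trial", subject_id, activity, repetition)
    traits = _subject_traits(config, subject_id)
    n = int(np.ceil(config.trial_duration_s * 1000.0 / config.sampling_period_ms))
    t = np.arange(n) * config.sampling_period_ms / 1000.0

    wrist, hip, wgyro, hgyro, _span = _activity_envelope(activity, t, rng, config, traits)
    g = config.gravity_ms2
    gravity = np.array([0.0, 0.0, g])
    wA = wrist + gravity + rng.normal(0.0, config.noise_sd, (n, 3))
    hA = hip + gravity + rng.normal(0.0, config.noise_sd, (n, 3))
    wG = wgyro + rng.normal(0.0, config.gyro_noise_sd, (n, 3))
    hG = hgyro + rng.normal(0.0, config.gyro_noise_sd, (n, 3))

    ts_wrist = _timestamps(n, config, rng)
    ts_hip = _timestamps(n, config, rng)
    tracks = {
        (Site.WRIST, Modality.ACCELEROMETER): SensorTrack(Site.WRIST, Modality.ACCELEROMETER, ts_wrist, wA),
        (Site.WRIST, Modality.GYROSCOPE): SensorTrack(Site.WRIST, Modality.GYROSCOPE, ts_wrist, wG),
        (Site.HIP, Modality.ACCELEROMETER): SensorTrack(Site.HIP, Modality.ACCELEROMETER, ts_hip, hA),
        (Site.HIP, Modality.GYROSCOPE): SensorTrack(Site.HIP, Modality.GYROSCOPE, ts_hip, hG),
    }
    return Trial(subject_id=subject_id, activity=activity, tracks=tracks, repetition=repetition)


def generate_cohort(
    n_subjects: int,
    reps: int,
    config: GeneratorConfig,
    out_dir: str | Path | None = None,
    *,
    overwrite: bool = False,
) -> DatasetIndex:
    """Generate the full protocol: 5 fall types + 8 ADLs, ``reps`` each,
    per subject.  With 16 subjects and 5 reps this yields 400 fall and 640
    ADL trials.  If ``out_dir`` is given, trials are also written to disk in
    the standard layout.
    """
    if n_subjects < 1 or reps < 1:
        raise ValueError("n_subjects and reps must be >= 1")
    trials = []
    for s in range(n_subjects):
        subject_id = f"S{s + 1:02d}"
        for activity in FALL_ACTIVITIES + ADL_ACTIVITIES:
            for rep in range(1, reps + 1):
                trial = generate_trial(activity, subject_id, config, repetition=rep)
                if out_dir is not None:
                    save_trial_csv(trial, out_dir, overwrite=overwrite)
                trials.append(trial)
    return DatasetIndex(trials)


@dataclass(frozen=True)
class StreamAnnotation:
    """Ground-truth extent of one scheduled event in a continuous stream."""

    start_ms: int
    end_ms: int
    activity: str

    @property
    def is_fall(self) -> bool:
        return self.activity in FALL_ACTIVITIES


@dataclass
class Stream:
    """A continuous four-channel recording with ground-truth annotations.

    ``values`` holds the 12 columns (wA, wG, hA, hG) x (x, y, z) in canonical
    channel order on a single shared time grid.
    """

    timestamps: np.ndarray  # (T,) ms
    values: np.ndarray  # (T, 12)
    annotations: list[StreamAnnotation] = field(default_factory=list)
    subject_id: str = "S01"

    def channel_matrix(self, combo) -> np.ndarray:
        """Columns for a :class:`~fallstream.windowing.SensorCombo`."""
        cols = []
        for ch in combo.channels:
            base = 3 * ("wA", "wG", "hA", "hG").index(ch)
            cols.extend(range(base, base + 3))
        return self.values[:, cols]


def generate_stream(
    duration_s: float,
    event_schedule: list[tuple[float, str]],
    config: GeneratorConfig,
    *,
    subject_id: str = "S01",
    stream_seed: int = 0,
    background: str = "mixed",
) -> Stream:
    """Simulate continuous wear: low-amplitude background with scheduled events.

    ``event_schedule`` is a list of (onset seconds, activity) pairs; activities
    may be any trial-vocabulary name or a stream-only ambiguous activity.
    Events must not overlap.  Background alternates quiet sitting with gentle
    walking (``background="mixed"``), or stays quiet (``"quiet"``).
    """
    rng = _derive_rng(config, "stream", subject_id, stream_seed)
    traits = _subject_traits(config, subject_id)
    n = int(np.ceil(duration_s * 1000.0 / config.sampling_period_ms))
    t = np.arange(n) * config.sampling_period_ms / 1000.0
    g = config.gravity_ms2

    wrist = np.zeros((n, 3))
    hip = np.zeros((n, 3))
    wgyro = np.zeros((n, 3))
    hgyro = np.zeros((n, 3))

    if background == "mixed":
        # Gentle walking bouts every other ~30 s block.
        block = 30.0
        freq = 1.8 * traits.frequency
        walk_gate = ((t // block).astype(int) % 2 == 1).astype(float)
        swing = np.sin(2 * np.pi * freq * t)
        dh = np.array([0.5, 0.2, 0.84]) / np.linalg.norm([0.5, 0.2, 0.84])
        hip += 1.8 * (walk_gate * swing)[:, None] * dh
        wrist += 2.2 * (walk_gate * np.sin(2 * np.pi * freq * t + 0.9))[:, None] * dh
        wgyro += 0.6 * (walk_gate * np.abs(swing))[:, None] * np.array([0.5, 0.5, 0.6])
        hgyro += 0.4 * (walk_gate * np.abs(swing))[:, None] * np.array([0.5, 0.5, 0.6])

    annotations: list[StreamAnnotation] = []
    last_end = -np.inf
    for onset_s, activity in sorted(event_schedule):
        if activity not in ACTIVITY_VOCABULARY + STREAM_ONLY_ACTIVITIES:
            raise VocabularyError(f"unknown activity {activity!r}")
        if activity in FALL_ACTIVITIES:
            dur = 8.0  # impact plus several seconds down before getting up
        elif activity == "lie_down":
            dur = 8.0
        else:
            dur = 4.0
        if onset_s < last_end:
            raise ValueError(
                f"scheduled event {activity!r} at {onset_s} s overlaps the previous event"
            )
        if onset_s + dur > duration_s:
            raise ValueError(f"event {activity!r} at {onset_s} s does not fit in the stream")
        ev_rng = _derive_rng(config, "stream-event", subject_id, stream_seed, onset_s, activity)
        if activity in FALL_ACTIVITIES:
            # In a stream the subject gets up again at the end of the event.
            w, h, wg, hg, span = _fall_envelope(
                t, ev_rng, config, traits, activity,
                t_impact=onset_s + 0.8, lie_until=onset_s + dur - 0.8,
            )
        else:
            w, h, wg, hg, span = _activity_envelope(
                activity, t, ev_rng, config, traits, start=onset_s, duration=dur - 1.0
            )
        wrist += w
        hip += h
        wgyro += wg
        hgyro += hg
        annotations.append(
            StreamAnnotation(
                start_ms=int(round(onset_s * 1000)),
                end_ms=int(round((onset_s + dur) * 1000)),
                activity=activity,
            )
        )
        last_end = onset_s + dur

    gravity = np.array([0.0, 0.0, g])
    values = np.concatenate(
        [
            wrist + gravity + rng.normal(0.0, config.noise_sd, (n, 3)),
            wgyro + rng.normal(0.0, config.gyro_noise_sd, (n, 3)),
            hip + gravity + rng.normal(0.0, config.noise_sd, (n, 3)),
            hgyro + rng.normal(0.0, config.gyro_noise_sd, (n, 3)),
        ],
        axis=1,
    )
    ts = _timestamps(n, config, rng)
    return Stream(timestamps=ts, values=values, annotations=annotations, subject_id=subject_id)
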