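"""Real-time simulation of on-device inference.

Samples arrive one row at a time into a ring buffer.  The first prediction
fires once `window_size` rows have accumulated; every later prediction needs
only `step_size` fresh rows, reusing all previous rows except the least
recent.  Raw per-window probabilities are smoothed by averaging the last
`n_smooth` values (default 10) and compared against a threshold (default
0.5, strict `>`): the average suppresses isolated positive predictions so a
single spiky window cannot raise a false alarm.  After an alarm the
probability history restarts by default, so one fall yields one alarm.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .datamodel import FeedbackEvent, FeedbackKind, FeedbackSource
from .windowing import SensorCombo, WindowingConfig

__all__ = [
    "TriggerConfig",
    "PredictionTrace",
    "StreamingEngine",
    "smooth_and_decide",
    "evaluate_stream",
    "StreamCounts",
    "capture_feedback",
]


class RefractoryPolicy(str, Enum):
    CLEAR_BUFFER = "clear_buffer"
    NONE = "none"


@dataclass(frozen=True)
class TriggerConfig:
    n_smooth: int = 10
    threshold: float = 0.5
    refractory_policy: RefractoryPolicy = RefractoryPolicy.CLEAR_BUFFER

    def __post_init__(self) -> None:
        if self.n_smooth < 1:
            raise ValueError("n_smooth must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class PredictionTrace:
    """Per-prediction record of a streaming run.

    ``smoothed[i]`` is the mean of the last ``n_smooth`` raw probabilities
    ending at ``i``; it is NaN until enough predictions exist (and again
    right after an alarm under the clear-buffer policy).  Every trigger's
    smoothed value strictly exceeds the threshold.
    """

    step_times: list[int] = field(default_factory=list)  # ms
    raw_probabilities: list[float] = field(default_factory=list)
    smoothed: list[float] = field(default_factory=list)
    triggers: list[tuple[int, float]] = field(default_factory=list)  # (time ms, smoothed)

    @property
    def trigger_times(self) -> list[int]:
        return [t for t, _ in self.triggers]


def smooth_and_decide(raw: list[float], config: TriggerConfig) -> PredictionTrace:
    """Apply the n-probability moving-average trigger to a raw trace.

    With the clear-buffer policy the history restarts after every trigger,
    so the next alarm needs ``n_smooth`` fresh predictions.  Step times are
    the raw indices; use :class:`StreamingEngine` for wall-clock times.
    """
    trace = PredictionTrace()
    history: deque[float] = deque(maxlen=config.n_smooth)
    for i, p in enumerate(raw):
        p = float(p)
        history.append(p)
        trace.step_times.append(i)
        trace.raw_probabilities.append(p)
        if len(history) == config.n_smooth:
            mean = float(np.mean(history))
            trace.smoothed.append(mean)
            if mean > config.threshold:
                trace.triggers.append((i, mean))
                if config.refractory_policy is RefractoryPolicy.CLEAR_BUFFER:
                    history.clear()
        else:
            trace.smoothed.append(float("nan"))
    return trace


class StreamingEngine:
    """Ring-buffered on-line inference bound to a trained model and combo."""

    def __init__(
        self,
        model,
        combo: SensorCombo,
        windowing: WindowingConfig | None = None,
        trigger: TriggerConfig | None = None,
    ):
        self.model = model
        self.combo = combo
        self.windowing = windowing or WindowingConfig()
        self.trigger = trigger or TriggerConfig()
        if model.input_width != combo.width:
            raise ValueError(
                f"model expects width {model.input_width} but combo {combo} has {combo.width}"
            )
        self._buffer: deque[np.ndarray] = deque(maxlen=self.windowing.window_size)
        self._since_last = 0
        self._primed = False
        self._history: deque[float] = deque(maxlen=self.trigger.n_smooth)
        self.trace = PredictionTrace()

    def push_samples(self, rows: np.ndarray, times_ms: np.ndarray) -> list[float]:
        """Feed new multichannel rows; returns any new raw probabilities.

        The first prediction fires exactly when ``window_size`` rows have
        been buffered; each subsequent one after ``step_size`` further rows.
        """
        rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
        times_ms = np.atleast_1d(np.asarray(times_ms))
        if rows.shape[1] != self.combo.width:
            raise ValueError(
                f"row width {rows.shape[1]} does not match combo width {self.combo.width}"
            )
        if len(rows) != len(times_ms):
            raise ValueError("rows and times_ms must have equal length")
        new: list[float] = []
        for row, t in zip(rows, times_ms):
            self._buffer.append(row)
            if not self._primed:
                if len(self._buffer) == self.windowing.window_size:
                    self._primed = True
                    new.append(self._predict(int(t)))
            else:
                self._since_last += 1
                if self._since_last == self.windowing.step_size:
                    self._since_last = 0
                    new.append(self._predict(int(t)))
        return new

    def _predict(self, t_ms: int) -> float:
        window = np.stack(self._buffer)
        p = self.model.predict_window(window)
        self.trace.step_times.append(t_ms)
        self.trace.raw_probabilities.append(p)
        self._history.append(p)
        if len(self._history) == self.trigger.n_smooth:
            mean = float(np.mean(self._history))
            self.trace.smoothed.append(mean)
            if mean > self.trigger.threshold:
                self.trace.triggers.append((t_ms, mean))
                if self.trigger.refractory_policy is RefractoryPolicy.CLEAR_BUFFER:
                    self._history.clear()
        else:
            self.trace.smoothed.append(float("nan"))
        return p

    def current_window(self) -> np.ndarray:
        if len(self._buffer) < self.windowing.window_size:
            raise ValueError("buffer not yet full")
        return np.stack(self._buffer)


@dataclass
class StreamCounts:
    tp: int
    fp: int
    fn: int


def _run_engine(model, stream, combo, windowing, trigger) -> tuple[StreamingEngine, PredictionTrace]:
    engine = StreamingEngine(model, combo, windowing, trigger)
    engine.push_samples(stream.channel_matrix(combo), stream.timestamps)
    return engine, engine.trace


def evaluate_stream(
    model,
    stream,
    combo: SensorCombo,
    windowing: WindowingConfig | None = None,
    trigger: TriggerConfig | None = None,
    match_window_s: float = 10.0,
) -> tuple[StreamCounts, PredictionTrace]:
    """Event-level evaluation of a model on an annotated stream.

    A trigger within ``match_window_s`` of an annotated fall onset is a TP
    (first match wins); leftover triggers are FPs; unmatched annotated falls
    are FNs.
    """
    windowing = windowing or WindowingConfig()
    _, trace = _run_engine(model, stream, combo, windowing, trigger or TriggerConfig())
    fall_onsets = [a.start_ms for a in stream.annotations if a.is_fall]
    tol = match_window_s * 1000.0
    unmatched = list(trace.trigger_times)
    tp = fn = 0
    for onset in fall_onsets:
        hit = next((t for t in unmatched if abs(t - onset) <= tol), None)
        if hit is None:
            fn += 1
        else:
            tp += 1
            unmatched.remove(hit)
    return StreamCounts(tp=tp, fp=len(unmatched), fn=fn), trace


def capture_feedback(
    model,
    stream,
    combo: SensorCombo,
    decisions: list[bool] | None = None,
    user_reported_falls_ms: list[int] | None = None,
    windowing: WindowingConfig | None = None,
    trigger: TriggerConfig | None = None,
    tn_every_s: float = 60.0,
    match_window_s: float = 10.0,
) -> tuple[list[FeedbackEvent], PredictionTrace]:
    """Simulate the deployed feedback loop on an annotated stream.

    ``decisions`` is one user response per trigger ("did you fall?"); when
    omitted, a truthful user is simulated from the stream's annotations.
    Confirmed triggers yield TP events; rejected ones FP events.  A
    user-reported missed fall yields an FN event whose payload spans the
    window ending at the report plus the preceding window.  One background
    window per ``tn_every_s`` of non-trigger streaming is harvested as TN.
    """
    windowing = windowing or WindowingConfig()
    trigger = trigger or TriggerConfig()
    _, trace = _run_engine(model, stream, combo, windowing, trigger)
    matrix = stream.channel_matrix(combo)
    ts = stream.timestamps
    W = windowing.window_size
    tol = match_window_s * 1000.0
    fall_onsets = [a.start_ms for a in stream.annotations if a.is_fall]

    if decisions is None:
        decisions = [
            any(abs(t - onset) <= tol for onset in fall_onsets)
            for t in trace.trigger_times
        ]
    if len(decisions) != len(trace.triggers):
        raise ValueError(
            f"{len(decisions)} user responses for {len(trace.triggers)} triggers"
        )

    if user_reported_falls_ms is None:
        matched: list[int] = []
        pool = [t for t, d in zip(trace.trigger_times, decisions) if d]
        for onset in fall_onsets:
            hit = next((t for t in pool if abs(t - onset) <= tol), None)
            if hit is not None:
                pool.remove(hit)
                matched.append(onset)
        user_reported_falls_ms = [o for o in fall_onsets if o not in matched]

    def window_ending_at(t_ms: int, length: int) -> np.ndarray | None:
        end = int(np.searchsorted(ts, t_ms, side="right"))
        if end < length:
            return None
        return matrix[end - length : end]

    events: list[FeedbackEvent] = []
    for (t_ms, _), yes in zip(trace.triggers, decisions):
        payload = window_ending_at(t_ms, W)
        if payload is None:
            continue
        events.append(
            FeedbackEvent(
                kind=FeedbackKind.TP if yes else FeedbackKind.FP,
                window_payload=payload,
                subject_id=stream.subject_id,
                timestamp_ms=t_ms,
                source=FeedbackSource.TRIGGER_CONFIRMED if yes else FeedbackSource.TRIGGER_REJECTED,
            )
        )
    for onset in user_reported_falls_ms:
        report_ms = onset + int(2000)  # user presses the button shortly after
        payload = window_ending_at(report_ms, 2 * W)
        if payload is None:
            payload = window_ending_at(report_ms, W)
        if payload is None:
            continue
        events.append(
            FeedbackEvent(
                kind=FeedbackKind.FN,
                window_payload=payload,
                subject_id=stream.subject_id,
                timestamp_ms=report_ms,
                source=FeedbackSource.USER_REPORTED_FALL,
            )
        )
    # Periodic TN harvest from non-trigger stretches.
    step_ms = tn_every_s * 1000.0
    avoid = sorted(trace.trigger_times + fall_onsets)
    next_tn = step_ms
    horizon = float(ts[-1]) if len(ts) else 0.0
    while next_tn <= horizon:
        t_ms = int(next_tn)
        if all(abs(t_ms - a) > tol for a in avoid):
            payload = window_ending_at(t_ms, W)
            if payload is not None:
                events.append(
                    FeedbackEvent(
                        kind=FeedbackKind.TN,
                        window_payload=payload,
                        subject_id=stream.subject_id,
                        timestamp_ms=t_ms,
                        source=FeedbackSource.BACKGROUND,
                    )
                )
        next_tn += step_ms
    events.sort(key=lambda e: e.timestamp_ms)
    return events, trace
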