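"""Ring-buffer cadence, the moving-average trigger and feedback capture."""

import numpy as np
import pytest

from fallstream.datamodel import FeedbackKind
from fallstream.streaming import (
    RefractoryPolicy,
    StreamingEngine,
    TriggerConfig,
    capture_feedback,
    evaluate_stream,
    smooth_and_decide,
)
from fallstream.synthetic import Stream, StreamAnnotation
from fallstream.windowing import SensorCombo, WindowingConfig, segment


class SpikeModel:
    """Stub classifier: fall probability 1 when channel 0 mean exceeds 0.5."""

    def __init__(self, input_width=3):
        self.input_width = input_width

    def predict_window(self, window):
        return 1.0 if float(np.mean(window[:, 0])) > 0.5 else 0.0

    def predict_proba(self, windows):
        return np.array([self.predict_window(w) for w in windows])


def _quiet_stream(duration_s=120.0, period_ms=32, annotations=(), hot=()):
    """All-zero 12-channel stream; `hot` lists (start_s, end_s) spans where
    channel 0 is driven to 1 (lighting up SpikeModel)."""
    n = int(duration_s * 1000 / period_ms)
    ts = np.arange(n) * period_ms
    values = np.zeros((n, 12))
    for start_s, end_s in hot:
        values[(ts >= start_s * 1000) & (ts < end_s * 1000), 0] = 1.0
    return Stream(timestamps=ts, values=values, annotations=list(annotations))


class TestPushSamples:
    def _engine(self, trigger=None):
        return StreamingEngine(
            SpikeModel(), SensorCombo("wA"), WindowingConfig(128, 32), trigger or TriggerConfig()
        )

    def test_first_prediction_at_window_size(self):
        eng = self._engine()
        rows = np.zeros((127, 3))
        assert eng.push_samples(rows, np.arange(127)) == []
        assert len(eng.push_samples(np.zeros((1, 3)), [127])) == 1

    def test_prediction_every_step(self):
        eng = self._engine()
        out = eng.push_samples(np.zeros((160, 3)), np.arange(160))
        assert len(out) == 2  # at row 128 and row 160

    def test_width_mismatch(self):
        eng = self._engine()
        with pytest.raises(ValueError, match="width"):
            eng.push_samples(np.zeros((10, 6)), np.arange(10))

    def test_fresh_engines_identical(self):
        rows = np.random.default_rng(1).normal(size=(200, 3))
        out1 = self._engine().push_samples(rows, np.arange(200))
        out2 = self._engine().push_samples(rows, np.arange(200))
        assert out1 == out2


def brute_force_triggers(raw, n, threshold):
    """Rolling-mean threshold scan without refractory behaviour."""
    return [
        i
        for i in range(n - 1, len(raw))
        if float(np.mean(raw[i - n + 1 : i + 1])) > threshold
    ]


class TestSmoothAndDecide:
    def test_constant_point_six_triggers_at_nine(self):
        trace = smooth_and_decide([0.6] * 10, TriggerConfig())
        assert [t for t, _ in trace.triggers] == [9]
        assert trace.triggers[0][1] == pytest.approx(0.6)

    def test_isolated_positive_suppressed(self):
        # a lone 1.0 averages to 0.1 over ten steps: no false alarm
        trace = smooth_and_decide([1.0] + [0.0] * 9, TriggerConfig())
        assert trace.triggers == []

    def test_alternating_means_stay_below_threshold(self):
        raw = [0.9, 0.0] * 10
        trace = smooth_and_decide(raw, TriggerConfig())
        assert trace.triggers == []
        assert trace.smoothed[-1] == pytest.approx(0.45)

    def test_clear_buffer_requires_fresh_history(self):
        raw = [0.6] * 25
        clear = smooth_and_decide(raw, TriggerConfig())
        assert [t for t, _ in clear.triggers] == [9, 19]
        keep = smooth_and_decide(raw, TriggerConfig(refractory_policy=RefractoryPolicy.NONE))
        assert [t for t, _ in keep.triggers] == list(range(9, 25))

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(42)
        cfg_none = TriggerConfig(refractory_policy=RefractoryPolicy.NONE)
        for _ in range(300):
            raw = rng.random(rng.integers(1, 40)).tolist()
            trace = smooth_and_decide(raw, cfg_none)
            assert [t for t, _ in trace.triggers] == brute_force_triggers(raw, 10, 0.5)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        raw = rng.random(200).tolist()
        counts = [
            len(smooth_and_decide(raw, TriggerConfig(threshold=th)).triggers)
            for th in (0.2, 0.4, 0.6, 0.8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_smoothed_is_mean_of_last_n(self):
        rng = np.random.default_rng(3)
        raw = rng.random(30).tolist()
        trace = smooth_and_decide(raw, TriggerConfig(n_smooth=5, threshold=0.99))
        for i in range(4, 30):
            assert trace.smoothed[i] == pytest.approx(np.mean(raw[i - 4 : i + 1]))
        assert all(np.isnan(v) for v in trace.smoothed[:4])


class TestOnlineOfflineEquivalence:
    def test_streaming_equals_offline_segmentation(self):
        rng = np.random.default_rng(5)
        n = 500
        stream = _quiet_stream(duration_s=n * 0.032)
        stream.values[:, 0:3] = rng.normal(size=(n, 3))
        from fallstream.transformer import FallTransformer, TransformerConfig

        model = FallTransformer(
            TransformerConfig(n_layers=1, n_heads=2, d_model=16, dropout=0.25), input_width=3, seed=0
        )
        combo, wc = SensorCombo("wA"), WindowingConfig(128, 32)
        eng = StreamingEngine(model, combo, wc)
        online = eng.push_samples(stream.channel_matrix(combo), stream.timestamps)
        windows, _ = segment(stream.channel_matrix(combo), wc)
        offline = model.predict_proba(windows)
        np.testing.assert_allclose(online, offline, atol=1e-6)


class TestEvaluateStream:
    def test_matched_fall_is_tp(self):
        ann = [StreamAnnotation(30000, 38000, "front")]
        stream = _quiet_stream(annotations=ann, hot=[(28, 36)])
        counts, trace = evaluate_stream(SpikeModel(), stream, SensorCombo("wA"))
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)
        assert len(trace.triggers) >= 1

    def test_unmatched_triggers_are_fp(self):
        stream = _quiet_stream(hot=[(20, 28), (80, 88)])
        counts, _ = evaluate_stream(SpikeModel(), stream, SensorCombo("wA"))
        assert counts.tp == 0 and counts.fn == 0 and counts.fp == 2

    def test_two_falls_one_matched(self):
        ann = [
            StreamAnnotation(20000, 28000, "left"),
            StreamAnnotation(90000, 98000, "right"),
        ]
        stream = _quiet_stream(annotations=ann, hot=[(18, 26)])  # only first fall detected
        counts, _ = evaluate_stream(SpikeModel(), stream, SensorCombo("wA"))
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 1)


class TestCaptureFeedback:
    def test_user_responses_label_triggers(self):
        stream = _quiet_stream(hot=[(20, 28), (60, 68), (100, 108)])
        events, trace = capture_feedback(
            SpikeModel(), stream, SensorCombo("wA"),
            decisions=[True, False, False], tn_every_s=1e9,
        )
        kinds = [e.kind for e in events]
        assert kinds.count(FeedbackKind.TP) == 1
        assert kinds.count(FeedbackKind.FP) == 2
        assert len(trace.triggers) == 3

    def test_response_count_mismatch(self):
        stream = _quiet_stream(hot=[(20, 28)])
        with pytest.raises(ValueError, match="responses"):
            capture_feedback(SpikeModel(), stream, SensorCombo("wA"), decisions=[True, False])

    def test_missed_fall_becomes_fn_with_double_window(self):
        ann = [StreamAnnotation(30000, 38000, "front")]
        stream = _quiet_stream(annotations=ann)  # model never fires
        events, _ = capture_feedback(SpikeModel(), stream, SensorCombo("wA"), tn_every_s=1e9)
        fns = [e for e in events if e.kind is FeedbackKind.FN]
        assert len(fns) == 1
        assert fns[0].window_payload.shape == (256, 3)
        assert fns[0].retrain_label == 1

    def test_tn_harvest_cadence(self):
        stream = _quiet_stream(duration_s=600)
        events, _ = capture_feedback(SpikeModel(), stream, SensorCombo("wA"), tn_every_s=60.0)
        tns = [e for e in events if e.kind is FeedbackKind.TN]
        assert len(tns) == 9  # one per minute once a full window exists, t=60..540
        assert all(e.window_payload.shape == (128, 3) for e in tns)

    def test_truthful_user_simulation(self):
        ann = [StreamAnnotation(30000, 38000, "front")]
        stream = _quiet_stream(annotations=ann, hot=[(28, 36), (80, 88)])
        events, _ = capture_feedback(SpikeModel(), stream, SensorCombo("wA"), tn_every_s=1e9)
        kinds = sorted(e.kind.value for e in events)
        assert kinds == ["FP", "TP"]


def test_trigger_config_validation():
    with pytest.raises(ValueError):
        TriggerConfig(n_smooth=0)
    with pytest.raises(ValueError):
        TriggerConfig(threshold=1.0)
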