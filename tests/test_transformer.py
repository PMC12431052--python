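"""Attention oracles, gradient checks and training contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fallstream.transformer import (
    DegenerateDataError,
    FallTransformer,
    TrainSpec,
    TransformerConfig,
    attention,
    load_checkpoint,
    multi_head_attention,
    save_checkpoint,
    train,
)
from fallstream.windowing import WindowBatch


def brute_force_attention(Q, K, V):
    """Literal double-loop scaled dot-product attention."""
    n, d_k = Q.shape
    m, d_v = V.shape[0], V.shape[1]
    out = np.zeros((n, d_v))
    for i in range(n):
        scores = np.array([Q[i] @ K[j] / np.sqrt(d_k) for j in range(m)])
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        for j in range(m):
            out[i] += w[j] * V[j]
    return out


class TestAttention:
    def test_single_key_returns_value_row(self, rng):
        Q = rng.normal(size=(4, 3))
        K = rng.normal(size=(1, 3))
        V = rng.normal(size=(1, 5))
        np.testing.assert_allclose(attention(Q, K, V), np.tile(V, (4, 1)), atol=1e-12)

    def test_orthogonal_query_gives_value_mean(self):
        Q = np.zeros((2, 3))
        K = np.eye(3)
        V = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        np.testing.assert_allclose(attention(Q, K, V), np.tile(V.mean(axis=0), (2, 1)), atol=1e-12)

    def test_hand_computed_two_key_example(self):
        # softmax(2, -2) weights give e^2/(e^2+e^-2) ~= 0.982 on V=[1,0]
        out = attention(np.array([[2.0]]), np.array([[1.0], [-1.0]]), np.array([[1.0], [0.0]]))
        expected = np.exp(2) / (np.exp(2) + np.exp(-2))
        assert out[0, 0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.982, abs=1e-3)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            attention(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)), rng.normal(size=(2, 2)))
        with pytest.raises(ValueError):
            attention(rng.normal(size=(2, 3)), rng.normal(size=(4, 3)), rng.normal(size=(3, 2)))

    @given(
        n=st.integers(1, 8), m=st.integers(1, 8),
        d_k=st.integers(1, 4), d_v=st.integers(1, 4),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=150)
    def test_matches_brute_force(self, n, m, d_k, d_v, seed):
        rng = np.random.default_rng(seed)
        Q, K, V = rng.normal(size=(n, d_k)), rng.normal(size=(m, d_k)), rng.normal(size=(m, d_v))
        np.testing.assert_allclose(attention(Q, K, V), brute_force_attention(Q, K, V), atol=1e-6)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=100)
    def test_softmax_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        Q, K = rng.normal(size=(5, 3)), rng.normal(size=(7, 3))
        # rows of softmax weights sum to 1 <=> attention over all-ones V is 1
        out = attention(Q, K, np.ones((7, 1)))
        np.testing.assert_allclose(out, 1.0, atol=1e-6)


class TestMultiHeadAttention:
    def _identity_params(self, d):
        eye, zero = np.eye(d), np.zeros(d)
        return {f"{p}W": eye.copy() for p in "qkvo"} | {f"{p}b": zero.copy() for p in "qkvo"}

    def test_single_head_identity_reduces_to_attention(self, rng):
        X = rng.normal(size=(6, 4))
        out = multi_head_attention(X, self._identity_params(4), n_heads=1)
        np.testing.assert_allclose(out, attention(X, X, X), atol=1e-9)

    def test_output_shape_preserved(self, rng):
        d = 128
        params = self._identity_params(d)
        X = rng.normal(size=(10, d))
        assert multi_head_attention(X, params, n_heads=4).shape == (10, d)

    def test_zero_input_constant_rows(self, rng):
        d = 8
        params = {f"{p}W": rng.normal(size=(d, d)) for p in "qkvo"}
        params |= {f"{p}b": rng.normal(size=d) for p in "qkvo"}
        out = multi_head_attention(np.zeros((5, d)), params, n_heads=2)
        # constant input -> every row identical, equal to the bias-only pass
        np.testing.assert_allclose(out, np.tile(out[0], (5, 1)), atol=1e-9)
        hand = params["vb"] @ params["oW"] + params["ob"]
        np.testing.assert_allclose(out[0], hand, atol=1e-9)


class TestEncoderForward:
    def test_probability_in_open_interval(self, tiny_model_config, rng):
        model = FallTransformer(tiny_model_config, input_width=6, seed=0)
        p = model.predict_window(rng.normal(size=(128, 6)))
        assert 0.0 < p < 1.0

    def test_inference_deterministic(self, tiny_model_config, rng):
        model = FallTransformer(tiny_model_config, input_width=6, seed=0)
        w = rng.normal(size=(128, 6))
        assert model.predict_window(w) == model.predict_window(w)

    def test_zero_weights_give_half(self, tiny_model_config, rng):
        model = FallTransformer(tiny_model_config, input_width=6, seed=0)
        for k, v in model.params.items():
            if not k.endswith(("ln1_g", "ln2_g")):  # layernorm gains stay at 1
                model.params[k] = np.zeros_like(v)
        assert model.predict_window(rng.normal(size=(128, 6))) == pytest.approx(0.5)

    def test_batch_padding_invariance(self, tiny_model_config, rng):
        model = FallTransformer(tiny_model_config, input_width=6, seed=0)
        batch = rng.normal(size=(5, 64, 6))
        alone = model.predict_window(batch[2])
        together = model.predict_proba(batch)[2]
        assert alone == pytest.approx(together, abs=1e-6)

    def test_width_mismatch_rejected(self, tiny_model_config, rng):
        model = FallTransformer(tiny_model_config, input_width=6, seed=0)
        with pytest.raises(ValueError, match="width"):
            model.predict_window(rng.normal(size=(128, 9)))


def test_default_parameter_count():
    """Architecture guard: the default config has a fixed parameter count."""
    cfg = TransformerConfig()
    C, d = 6, cfg.d_model
    per_layer = (
        4 * (d * d + d)  # q, k, v, o projections
        + 2 * 2 * d      # two layer norms
        + 2 * (d * d + d)  # position-wise FFN (hidden = d_model)
    )
    h1, h2 = cfg.head_ffn_dims
    expected = (
        (C * d + d)
        + cfg.n_layers * per_layer
        + (d * h1 + h1) + (h1 * h2 + h2) + (h2 * 1 + 1)
    )
    model = FallTransformer(cfg, input_width=C, seed=0)
    assert model.n_parameters() == expected == 400_425


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        cfg = TransformerConfig(n_layers=2, n_heads=2, d_model=8, dropout=0.0, head_ffn_dims=(3, 5))
        model = FallTransformer(cfg, input_width=4, seed=1, dtype=np.float64)
        X = rng.normal(size=(3, 9, 4))
        y = np.array([1.0, 0.0, 1.0])
        loss, grads = model.loss_and_grads(X, y)
        assert loss > 0
        eps = 1e-6
        check_rng = np.random.default_rng(2)
        for name in ("embed_W", "layer0_qW", "layer0_vW", "layer1_oW",
                     "layer1_f1W", "layer0_ln1_g", "head1_W", "out_W", "out_b"):
            flat = model.params[name].ravel()
            for i in check_rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = model.loss_and_grads(X, y)
                flat[i] = orig - eps
                lm, _ = model.loss_and_grads(X, y)
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[name].ravel()[i] == pytest.approx(numeric, abs=5e-7), name


def _toy_batch(n=60, width=4, seed=0):
    rng = np.random.default_rng(seed)
    windows = rng.normal(scale=0.5, size=(n, 32, width)).astype(np.float32)
    labels = np.zeros(n, dtype=np.int64)
    labels[: n // 2] = 1
    windows[: n // 2, 10:14, 0] += 6.0  # separable spike channel for the fall class
    return WindowBatch(windows=windows, labels=labels, provenance=[("toy", i) for i in range(n)])


class TestTraining:
    def test_determinism_same_seed_identical_weights(self, tiny_model_config):
        batch = _toy_batch()
        spec = TrainSpec(epochs=2, batch_size=16, seed=3, repeats=1)
        m1 = train(batch, spec, tiny_model_config).model
        m2 = train(batch, spec, tiny_model_config).model
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_single_class_rejected(self, tiny_model_config):
        batch = _toy_batch()
        bad = WindowBatch(batch.windows[:10], np.ones(10, dtype=np.int64))
        with pytest.raises(DegenerateDataError):
            train(bad, TrainSpec(epochs=1, repeats=1), tiny_model_config)

    def test_loss_decreases_on_separable_toy(self, tiny_model_config):
        result = train(_toy_batch(), TrainSpec(epochs=8, batch_size=16, seed=0, repeats=1), tiny_model_config)
        trace = result.loss_traces[0]
        assert trace[-1] < trace[0]

    def test_repeats_return_all_models(self, tiny_model_config):
        result = train(_toy_batch(), TrainSpec(epochs=1, batch_size=16, seed=5, repeats=2), tiny_model_config)
        assert result.seeds == [5, 6]
        assert len(result.models) == 2


def test_checkpoint_round_trip(tmp_path, tiny_model_config, rng):
    model = FallTransformer(tiny_model_config, input_width=6, seed=4)
    path = tmp_path / "model.ckpt.npz"
    save_checkpoint(model, path, combo_name="wA+hA")
    back, combo = load_checkpoint(path)
    assert combo == "wA+hA"
    w = rng.normal(size=(64, 6))
    assert back.predict_window(w) == pytest.approx(model.predict_window(w), abs=1e-12)


def test_config_validation():
    with pytest.raises(ValueError):
        TransformerConfig(d_model=10, n_heads=4)
    with pytest.raises(ValueError):
        TransformerConfig(dropout=1.0)
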