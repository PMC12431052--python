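"""Encoder-only Transformer fall classifier, in NumPy with hand-written backprop.

Architecture (for raw multichannel IMU windows):

    input (window_size x C) -> linear projection to d_model (+ sinusoidal
    positional encoding) -> n_layers x [multi-head self-attention -> add &
    norm -> position-wise FFN -> add & norm] -> temporal mean-pool ->
    Dense(8, ReLU) -> Dense(16) -> Dense(1, sigmoid)

Defaults: 4 encoder layers, 4 heads, embedding 128, dropout 0.25, trained
with binary cross-entropy.  The scaled dot-product attention is

    Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V

and heads are concatenated and projected by W^O.  The small 8->16 head
follows the deployed model's prediction module: ReLU between the two dense
maps, none after the second, then a single sigmoid neuron.

No deep-learning framework is used: parameters are plain float32 arrays,
gradients are derived analytically, and training uses Adam.  Gradient
correctness is guarded by finite-difference tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TransformerConfig",
    "TrainSpec",
    "DegenerateDataError",
    "attention",
    "multi_head_attention",
    "sinusoidal_encoding",
    "FallTransformer",
    "TrainResult",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


class DegenerateDataError(ValueError):
    """Training data containing a single class."""


@dataclass(frozen=True)
class TransformerConfig:
    n_layers: int = 4
    n_heads: int = 4
    d_model: int = 128
    dropout: float = 0.25
    head_ffn_dims: tuple[int, int] = (8, 16)

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if min(self.head_ffn_dims) < 1:
            raise ValueError("head_ffn_dims must be positive")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


@dataclass(frozen=True)
class TrainSpec:
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    repeats: int = 3

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


# ----------------------------------------------------------------- primitives


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _softmax_inplace(x: np.ndarray) -> np.ndarray:
    """Row softmax over the last axis, mutating ``x`` (a fresh temporary)."""
    np.subtract(x, x.max(axis=-1, keepdims=True), out=x)
    np.exp(x, out=x)
    np.divide(x, x.sum(axis=-1, keepdims=True), out=x)
    return x


def _softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    return p * (dp - (dp * p).sum(axis=-1, keepdims=True))


def _softmax_backward_inplace(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Like :func:`_softmax_backward` but mutates ``dp``."""
    s = np.einsum("...i,...i->...", dp, p)[..., None]
    np.subtract(dp, s, out=dp)
    np.multiply(dp, p, out=dp)
    return dp


def attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention for one head.

    ``Q`` is (n, d_k), ``K`` is (m, d_k), ``V`` is (m, d_v); the result is
    (n, d_v) with each output row a convex combination of V's rows.
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.ndim != 2 or K.ndim != 2 or V.ndim != 2:
        raise ValueError("Q, K, V must be 2-D matrices")
    if Q.shape[1] != K.shape[1]:
        raise ValueError(f"key width mismatch: Q has {Q.shape[1]}, K has {K.shape[1]}")
    if K.shape[0] != V.shape[0]:
        raise ValueError(f"K has {K.shape[0]} rows but V has {V.shape[0]}")
    weights = _softmax(Q @ K.T / np.sqrt(Q.shape[1]))
    return weights @ V


def multi_head_attention(X: np.ndarray, params: dict, n_heads: int) -> np.ndarray:
    """Multi-head self-attention over a (T, d_model) sequence.

    ``params`` holds the projections ``qW, qb, kW, kb, vW, vb, oW, ob``.
    Heads attend on disjoint d_model/n_heads slices of the projected Q/K/V
    and are concatenated then mapped by W^O; the shape is preserved.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be (T, d_model)")
    out, _ = _mha_forward(X[None], params, n_heads)
    return out[0]


def _split_heads(x: np.ndarray, h: int) -> np.ndarray:
    B, T, d = x.shape
    return x.reshape(B, T, h, d // h).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    B, h, T, dk = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, h * dk)


def _dense(x, W, b):
    return x @ W + b


def _dense_backward(x, W, g):
    # x: (..., din), g: (..., dout)
    xf = x.reshape(-1, x.shape[-1])
    gf = g.reshape(-1, g.shape[-1])
    return g @ W.T, xf.T @ gf, gf.sum(axis=0)


def _mha_forward(x: np.ndarray, p: dict, h: int):
    Q = _dense(x, p["qW"], p["qb"])
    K = _dense(x, p["kW"], p["kb"])
    V = _dense(x, p["vW"], p["vb"])
    Qh, Kh, Vh = (_split_heads(a, h) for a in (Q, K, V))
    dk = Qh.shape[-1]
    S = Qh @ Kh.transpose(0, 1, 3, 2)
    S *= 1.0 / np.sqrt(dk)
    P = _softmax_inplace(S)
    O = P @ Vh
    Oc = _merge_heads(O)
    out = _dense(Oc, p["oW"], p["ob"])
    cache = (x, Qh, Kh, Vh, P, Oc)
    return out, cache


def _mha_backward(gout: np.ndarray, p: dict, h: int, cache, grads: dict, prefix: str):
    x, Qh, Kh, Vh, P, Oc = cache
    dk = Qh.shape[-1]
    dOc, dW, db = _dense_backward(Oc, p["oW"], gout)
    grads[prefix + "oW"] += dW
    grads[prefix + "ob"] += db
    dO = _split_heads(dOc, h)
    dP = dO @ Vh.transpose(0, 1, 3, 2)
    dVh = P.transpose(0, 1, 3, 2) @ dO
    dS = _softmax_backward_inplace(P, dP)
    dS *= 1.0 / np.sqrt(dk)
    dQh = dS @ Kh
    dKh = dS.transpose(0, 1, 3, 2) @ Qh
    dx = np.zeros_like(x)
    for name, dproj in (("q", _merge_heads(dQh)), ("k", _merge_heads(dKh)), ("v", _merge_heads(dVh))):
        dxi, dW, db = _dense_backward(x, p[name + "W"], dproj)
        grads[prefix + name + "W"] += dW
        grads[prefix + name + "b"] += db
        dx += dxi
    return dx


_LN_EPS = 1e-5


def _layernorm_forward(x, gamma, beta):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return xhat * gamma + beta, (xhat, inv)


def _layernorm_backward(g, gamma, cache, grads, gname, bname):
    xhat, inv = cache
    grads[gname] += (g * xhat).sum(axis=tuple(range(g.ndim - 1)))
    grads[bname] += g.sum(axis=tuple(range(g.ndim - 1)))
    gx = g * gamma
    d = xhat.shape[-1]
    return inv * (gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True))


def sinusoidal_encoding(T: int, d_model: int) -> np.ndarray:
    """Fixed sine/cosine positional code (adds no learned parameters)."""
    pos = np.arange(T)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d_model)
    enc = np.zeros((T, d_model))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles[:, : d_model - d_model // 2])
    return enc


# ---------------------------------------------------------------------- model


class FallTransformer:
    """The binary fall/ADL classifier over fused raw IMU windows.

    ``dtype`` defaults to float32 (fast on CPU); float64 is available for
    numerical verification such as finite-difference gradient checks.
    """

    def __init__(
        self,
        config: TransformerConfig,
        input_width: int,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.config = config
        self.input_width = int(input_width)
        self.seed = int(seed)
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        d = config.d_model

        def glorot(shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return rng.uniform(-limit, limit, shape)

        self.params["embed_W"] = glorot((self.input_width, d))
        self.params["embed_b"] = np.zeros(d)
        for i in range(config.n_layers):
            pre = f"layer{i}_"
            for proj in ("q", "k", "v", "o"):
                self.params[pre + proj + "W"] = glorot((d, d))
                self.params[pre + proj + "b"] = np.zeros(d)
            self.params[pre + "ln1_g"] = np.ones(d)
            self.params[pre + "ln1_b"] = np.zeros(d)
            # Position-wise FFN with hidden width d_model (residual-compatible).
            self.params[pre + "f1W"] = glorot((d, d))
            self.params[pre + "f1b"] = np.zeros(d)
            self.params[pre + "f2W"] = glorot((d, d))
            self.params[pre + "f2b"] = np.zeros(d)
            self.params[pre + "ln2_g"] = np.ones(d)
            self.params[pre + "ln2_b"] = np.zeros(d)
        h1, h2 = config.head_ffn_dims
        self.params["head1_W"] = glorot((d, h1))
        self.params["head1_b"] = np.zeros(h1)
        self.params["head2_W"] = glorot((h1, h2))
        self.params["head2_b"] = np.zeros(h2)
        self.params["out_W"] = glorot((h2, 1))
        self.params["out_b"] = np.zeros(1)
        self.params = {k: v.astype(self.dtype) for k, v in self.params.items()}
        self._pos_cache: dict[int, np.ndarray] = {}

    # -- forward -------------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _dropout_mask(self, shape, rng):
        p = self.config.dropout
        if rng is None or p == 0:
            return None
        return ((rng.random(shape) >= p) / (1.0 - p)).astype(self.dtype)

    def _forward(self, X: np.ndarray, rng=None):
        """Full forward pass; returns probabilities and the backprop cache.

        ``rng`` enables dropout (training); inference passes ``rng=None`` and
        is deterministic.
        """
        P = self.params
        cfg = self.config
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 3:
            raise ValueError("input must be (batch, window_size, channels)")
        B, T, C = X.shape
        if C != self.input_width:
            raise ValueError(
                f"window width {C} does not match the trained combo width {self.input_width}"
            )
        cache: dict = {"X": X, "masks": {}}
        if T not in self._pos_cache:
            self._pos_cache[T] = sinusoidal_encoding(T, cfg.d_model).astype(self.dtype)
        z = _dense(X, P["embed_W"], P["embed_b"]) + self._pos_cache[T]
        m = self._dropout_mask(z.shape, rng)
        if m is not None:
            cache["masks"]["embed"] = m
            z = z * m
        cache["z0"] = z
        for i in range(cfg.n_layers):
            pre = f"layer{i}_"
            lp = {k: P[pre + k] for k in ("qW", "qb", "kW", "kb", "vW", "vb", "oW", "ob")}
            a, mha_cache = _mha_forward(z, lp, cfg.n_heads)
            m = self._dropout_mask(a.shape, rng)
            if m is not None:
                cache["masks"][pre + "attn"] = m
                a = a * m
            r1 = z + a
            z1, ln1_cache = _layernorm_forward(r1, P[pre + "ln1_g"], P[pre + "ln1_b"])
            hpre = _dense(z1, P[pre + "f1W"], P[pre + "f1b"])
            hact = np.maximum(hpre, 0.0)
            f = _dense(hact, P[pre + "f2W"], P[pre + "f2b"])
            m = self._dropout_mask(f.shape, rng)
            if m is not None:
                cache["masks"][pre + "ffn"] = m
                f = f * m
            r2 = z1 + f
            z2, ln2_cache = _layernorm_forward(r2, P[pre + "ln2_g"], P[pre + "ln2_b"])
            cache[pre] = (mha_cache, ln1_cache, z1, hpre, hact, ln2_cache)
            z = z2
        pooled = z.mean(axis=1)
        g1pre = _dense(pooled, P["head1_W"], P["head1_b"])
        g1 = np.maximum(g1pre, 0.0)
        g2 = _dense(g1, P["head2_W"], P["head2_b"])  # no activation before the sigmoid neuron
        logit = _dense(g2, P["out_W"], P["out_b"])[:, 0].astype(np.float64)
        prob = 1.0 / (1.0 + np.exp(-logit))
        cache.update(zT=z, pooled=pooled, g1pre=g1pre, g1=g1, g2=g2, prob=prob, T=T)
        return prob, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Deterministic inference probabilities for a (B, W, C) batch."""
        prob, _ = self._forward(np.asarray(X), rng=None)
        return prob

    def predict_window(self, window: np.ndarray) -> float:
        """Probability in (0, 1) that a single (W, C) window is a fall."""
        window = np.asarray(window)
        if window.ndim != 2:
            raise ValueError("a window must be 2-D (window_size x channels)")
        return float(self.predict_proba(window[None])[0])

    # -- backward ------------------------------------------------------------

    def loss_and_grads(self, X, y, rng=None):
        """Mean binary cross-entropy and analytic parameter gradients."""
        P = self.params
        cfg = self.config
        y = np.asarray(y, dtype=np.float64)
        prob, cache = self._forward(X, rng=rng)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))
        grads = {k: np.zeros_like(v) for k, v in P.items()}
        B = len(y)

        dlogit = ((prob - y) / B).astype(self.dtype)  # sigmoid + BCE combined
        dg2, dW, db = _dense_backward(cache["g2"], P["out_W"], dlogit[:, None])
        grads["out_W"] += dW
        grads["out_b"] += db
        dg1, dW, db = _dense_backward(cache["g1"], P["head2_W"], dg2)
        grads["head2_W"] += dW
        grads["head2_b"] += db
        dg1 = dg1 * (cache["g1pre"] > 0)
        dpooled, dW, db = _dense_backward(cache["pooled"], P["head1_W"], dg1)
        grads["head1_W"] += dW
        grads["head1_b"] += db
        T = cache["T"]
        dz = np.repeat(dpooled[:, None, :], T, axis=1) / T

        for i in reversed(range(cfg.n_layers)):
            pre = f"layer{i}_"
            mha_cache, ln1_cache, z1, hpre, hact, ln2_cache = cache[pre]
            dr2 = _layernorm_backward(dz, P[pre + "ln2_g"], ln2_cache, grads, pre + "ln2_g", pre + "ln2_b")
            df = dr2
            m = cache["masks"].get(pre + "ffn")
            if m is not None:
                df = df * m
            dhact, dW, db = _dense_backward(hact, P[pre + "f2W"], df)
            grads[pre + "f2W"] += dW
            grads[pre + "f2b"] += db
            dhpre = dhact * (hpre > 0)
            dz1_ffn, dW, db = _dense_backward(z1, P[pre + "f1W"], dhpre)
            grads[pre + "f1W"] += dW
            grads[pre + "f1b"] += db
            dz1 = dr2 + dz1_ffn
            dr1 = _layernorm_backward(dz1, P[pre + "ln1_g"], ln1_cache, grads, pre + "ln1_g", pre + "ln1_b")
            da = dr1
            m = cache["masks"].get(pre + "attn")
            if m is not None:
                da = da * m
            lp = {k: P[pre + k] for k in ("qW", "qb", "kW", "kb", "vW", "vb", "oW", "ob")}
            dz_attn = _mha_backward(da, lp, cfg.n_heads, mha_cache, grads, pre)
            dz = dr1 + dz_attn

        m = cache["masks"].get("embed")
        if m is not None:
            dz = dz * m
        _, dW, db = _dense_backward(cache["X"], P["embed_W"], dz)
        grads["embed_W"] += dW
        grads["embed_b"] += db
        return loss, grads


class _Adam:
    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ------------------------------------------------------------------- training


@dataclass
class TrainResult:
    models: list[FallTransformer]
    seeds: list[int]
    loss_traces: list[list[float]] = field(default_factory=list)

    @property
    def model(self) -> FallTransformer:
        return self.models[0]


def _train_once(windows, labels, spec: TrainSpec, config: TransformerConfig, seed: int):
    model = FallTransformer(config, input_width=windows.shape[-1], seed=seed)
    windows = np.asarray(windows, dtype=model.dtype)
    rng = np.random.default_rng(seed)
    opt = _Adam(model.params, lr=spec.learning_rate)
    n = len(labels)
    trace: list[float] = []
    for _epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            loss, grads = model.loss_and_grads(windows[idx], labels[idx], rng=rng)
            opt.step(model.params, grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return model, trace


def train(batch, spec: TrainSpec, config: TransformerConfig) -> TrainResult:
    """Train ``spec.repeats`` independent models on a window batch.

    Repeat ``r`` uses seed ``spec.seed + r`` for initialization, shuffling
    and dropout, so the whole procedure is reproducible.  Raises
    :class:`DegenerateDataError` when only one class is present (precision
    and recall would be undefined downstream).
    """
    labels = np.asarray(batch.labels, dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("training batch must contain both classes")
    windows = np.asarray(batch.windows)
    models, seeds, traces = [], [], []
    for r in range(spec.repeats):
        seed = spec.seed + r
        model, trace = _train_once(windows, labels, spec, config, seed)
        models.append(model)
        seeds.append(seed)
        traces.append(trace)
    return TrainResult(models=models, seeds=seeds, loss_traces=traces)


# ---------------------------------------------------------------- checkpoints


def save_checkpoint(model: FallTransformer, path: str | Path, combo_name: str = "") -> None:
    """Single-file archive holding config, weights and the combo identity."""
    cfg = model.config
    np.savez(
        path,
        __meta__=np.array(
            [
                cfg.n_layers,
                cfg.n_heads,
                cfg.d_model,
                cfg.head_ffn_dims[0],
                cfg.head_ffn_dims[1],
                model.input_width,
                model.seed,
            ],
            dtype=np.int64,
        ),
        __dropout__=np.array([cfg.dropout]),
        __combo__=np.array([combo_name]),
        **model.params,
    )


def load_checkpoint(path: str | Path) -> tuple[FallTransformer, str]:
    data = np.load(path, allow_pickle=False)
    meta = data["__meta__"]
    cfg = TransformerConfig(
        n_layers=int(meta[0]),
        n_heads=int(meta[1]),
        d_model=int(meta[2]),
        dropout=float(data["__dropout__"][0]),
        head_ffn_dims=(int(meta[3]), int(meta[4])),
    )
    model = FallTransformer(cfg, input_width=int(meta[5]), seed=int(meta[6]))
    for k in model.params:
        model.params[k] = data[k]
    return model, str(data["__combo__"][0])
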