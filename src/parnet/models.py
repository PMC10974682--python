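"""Model zoo: the dual-stream CNN + ESN classifier and its baselines.

The flagship architecture (PAR-Net) runs two parallel feature extractors over
the same (L x F) window of skeleton frames:

* a **spatial stream** of 1-D convolutions over time (64 filters of kernel 3,
  then 128 of kernel 1), a per-timestep dense layer of 128 units and a
  flatten;
* a **temporal stream** — a 32-unit echo-state reservoir whose final state
  summarises the window's dynamics.

The two stream outputs are concatenated, passed through a self-attention
feature-selection module, then a 64-unit ReLU dense layer and a softmax
output of ``n_classes`` units.  The baselines cover the standard solo and
stacked-hybrid alternatives; all share the same 64-unit head and training
recipe so that comparisons isolate the feature extractors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .esn import ReservoirConfig
from .nn import (Sequential, Dense, Conv1D, MaxPool1D, Flatten, LSTM, GRU,
                 Bidirectional, EchoState, SelfAttention, softmax)
from .nn.core import Layer

__all__ = [
    "ConvStreamSpec", "AttentionSpec", "ModelConfig", "ModelHandle",
    "BASELINES", "ALL_MODELS", "build_cnn_stream", "self_attention",
    "build_par_net", "build_baseline", "build_model",
]

BASELINES = ("MLP", "CNN", "LSTM", "BiLSTM", "ESN", "GRU", "BiGRU",
             "CNN-GRU", "CNN-LSTM", "CNN-ESN", "DualStream-NoAttention")
ALL_MODELS = BASELINES + ("PAR-Net",)


@dataclass(frozen=True)
class ConvStreamSpec:
    """Spatial-stream layout: conv layers as (filters, kernel) pairs, an
    optional max-pool between them, a per-timestep dense layer, flatten."""

    layers: tuple[tuple[int, int], ...] = ((64, 3), (128, 1))
    pool_size: int | None = None
    pool_stride: int | None = None
    dense_units: int = 128
    activation: str = "relu"

    def __post_init__(self):
        for filters, kernel in self.layers:
            if kernel < 1 or filters < 1:
                raise ValueError("conv filters and kernel sizes must be >= 1")


@dataclass(frozen=True)
class AttentionSpec:
    """Self-attention module configuration (see :class:`~parnet.nn.SelfAttention`)."""

    score_fn: str = "dense"
    rescale: bool = True


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to assemble one classifier for one window shape."""

    window_length: int
    feature_dim: int
    n_classes: int
    conv: ConvStreamSpec = field(default_factory=ConvStreamSpec)
    reservoir: ReservoirConfig = field(default_factory=ReservoirConfig)
    attention: AttentionSpec = field(default_factory=AttentionSpec)
    head_units: int = 64
    recurrent_units: int = 64   # baseline LSTM/GRU width
    mlp_units: tuple[int, ...] = (128,)
    esn_mode: str = "moments"   # reservoir trajectory summary (see EchoState)
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.window_length < 1 or self.feature_dim < 1:
            raise ValueError("window_length and feature_dim must be >= 1")

    def reservoir_for(self, input_dim: int) -> ReservoirConfig:
        seed = (self.seed * 1000003 + self.reservoir.seed + 17) % (2**31 - 1)
        return replace(self.reservoir, input_dim=input_dim, seed=seed)


def build_cnn_stream(spec: ConvStreamSpec, L: int, F: int,
                     rng: np.random.Generator | None = None
                     ) -> tuple[Sequential, int]:
    """Assemble the spatial stream; returns (layer stack, output width)."""
    rng = rng or np.random.default_rng(0)
    layers: list = []
    t, c = L, F
    for i, (filters, kernel) in enumerate(spec.layers):
        if t < kernel:
            raise ValueError(
                f"conv layer {i} (kernel {kernel}) does not fit the remaining "
                f"length {t}: window too short for the receptive field")
        layers.append(Conv1D(c, filters, kernel, spec.activation, rng,
                             name=f"conv{i}"))
        t, c = t - kernel + 1, filters
        if spec.pool_size is not None and i < len(spec.layers) - 1:
            if t < spec.pool_size:
                raise ValueError(
                    f"pool after conv layer {i} (size {spec.pool_size}) does "
                    f"not fit the remaining length {t}")
            stride = spec.pool_stride or spec.pool_size
            layers.append(MaxPool1D(spec.pool_size, stride, name=f"pool{i}"))
            t = (t - spec.pool_size) // stride + 1
    layers.append(Dense(c, spec.dense_units, spec.activation, rng,
                        name="stream_dense"))
    layers.append(Flatten())
    return Sequential(layers, name="cnn_stream"), t * spec.dense_units


def self_attention(features: np.ndarray, score_fn: str = "dense",
                   rng: np.random.Generator | None = None,
                   rescale: bool = True
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Functional self-attention over the timestamp axis of (B, T, D).

    Scores each timestamp per dimension, softmax-normalises over timestamps
    and reweights the features; returns (weighted features, weights).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 3:
        raise ValueError("features must be (batch, T, D)")
    layer = SelfAttention(features.shape[1], score_fn=score_fn,
                          rescale=rescale, rng=rng)
    out = layer.forward(features)
    return out, layer.last_weights


class _Identity(Layer):
    def forward(self, x, train=False):
        return x

    def backward(self, grad):
        return grad


class DualStreamNet(Layer):
    """Two parallel streams on the same window, concatenated, optionally
    attention-reweighted, then the shared dense head.  Emits logits."""

    def __init__(self, cnn_stream: Sequential, cnn_width: int,
                 esn_stream: EchoState, esn_width: int,
                 attention: Layer, head: Sequential):
        self.cnn_stream = cnn_stream
        self.esn_stream = esn_stream
        self.cnn_width = cnn_width
        self.esn_width = esn_width
        self.attention = attention
        self.head = head
        self.fused_width = cnn_width + esn_width

    def params(self):
        return (self.cnn_stream.params() + self.esn_stream.params()
                + self.attention.params() + self.head.params())

    def forward(self, x, train=False):
        a = self.cnn_stream.forward(x, train=train)
        b = self.esn_stream.forward(x, train=train)
        z = np.concatenate([a, b], axis=1)
        z = self.attention.forward(z, train=train)
        return self.head.forward(z, train=train)

    def backward(self, grad):
        dz = self.head.backward(grad)
        dz = self.attention.backward(dz)
        da, db = dz[:, :self.cnn_width], dz[:, self.cnn_width:]
        dx = self.cnn_stream.backward(da)
        dx = dx + self.esn_stream.backward(db)
        return dx


@dataclass
class ModelHandle:
    """An assembled classifier: name, network and its shape contract.

    ``forward`` maps a (batch, L, F) window batch to (batch, n_classes)
    probability rows (softmax applied)."""

    name: str
    net: Layer
    config: ModelConfig
    components: dict

    def forward(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = []
        for i in range(0, X.shape[0], batch_size):
            logits = self.net.forward(X[i:i + batch_size])
            out.append(softmax(logits))
        return np.concatenate(out, axis=0) if out else np.zeros(
            (0, self.config.n_classes))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(X), axis=1)

    @property
    def parameter_summary(self) -> dict:
        summary = dict(self.components)
        summary["total"] = sum(summary.values())
        return summary


def _head(rng, in_dim: int, config: ModelConfig) -> Sequential:
    """Shared classification head: Dense(head_units, ReLU) + softmax output."""
    return Sequential([
        Dense(in_dim, config.head_units, "relu", rng, name="head_dense"),
        Dense(config.head_units, config.n_classes, "linear", rng,
              name="head_out"),
    ], name="head")


def _count(layer: Layer) -> int:
    return int(sum(p.value.size for p in layer.params()))


def build_par_net(config: ModelConfig, with_attention: bool = True
                  ) -> ModelHandle:
    """Assemble the dual-stream attention classifier (or its no-attention
    ablation twin, identical apart from the attention block)."""
    rng = np.random.default_rng(config.seed)
    L, F = config.window_length, config.feature_dim
    cnn, cnn_w = build_cnn_stream(config.conv, L, F, rng)
    rcfg = config.reservoir_for(F)
    esn = EchoState(rcfg, mode=config.esn_mode, name="esn_stream")
    esn_w = esn.output_width
    fused = cnn_w + esn_w
    if with_attention:
        att: Layer = SelfAttention(fused, config.attention.score_fn,
                                   config.attention.rescale, rng)
    else:
        att = _Identity()
    head = _head(rng, fused, config)
    net = DualStreamNet(cnn, cnn_w, esn, esn_w, att, head)
    name = "PAR-Net" if with_attention else "DualStream-NoAttention"
    comps = {"cnn_stream": _count(cnn), "esn_stream": _count(esn),
             "attention": _count(att), "head": _count(head)}
    return ModelHandle(name, net, config, comps)


def _conv_trunk(config: ModelConfig, rng) -> tuple[list, int, int]:
    """Conv layers only (no dense/flatten) for the stacked hybrids."""
    layers: list = []
    t, c = config.window_length, config.feature_dim
    for i, (filters, kernel) in enumerate(config.conv.layers):
        if t < kernel:
            raise ValueError(
                f"conv layer {i} (kernel {kernel}) does not fit length {t}")
        layers.append(Conv1D(c, filters, kernel, config.conv.activation, rng,
                             name=f"conv{i}"))
        t, c = t - kernel + 1, filters
    return layers, t, c


def build_baseline(name: str, config: ModelConfig) -> ModelHandle:
    """Assemble one of the baseline architectures by name.

    All baselines share the Dense(head_units)+softmax head; the stacked
    hybrids (CNN-GRU / CNN-LSTM / CNN-ESN) feed conv features into the
    recurrent stage sequentially, and DualStream-NoAttention is the dual
    stream with the attention block replaced by the identity.
    """
    canon = {m.lower(): m for m in ALL_MODELS}
    key = canon.get(name.lower().replace("_", "-"))
    if key is None:
        raise ValueError(
            f"unknown model {name!r}; valid names: {', '.join(ALL_MODELS)}")
    if key == "PAR-Net":
        return build_par_net(config)
    if key == "DualStream-NoAttention":
        return build_par_net(config, with_attention=False)

    rng = np.random.default_rng(config.seed)
    L, F = config.window_length, config.feature_dim
    R = config.recurrent_units

    if key == "MLP":
        layers: list = [Flatten()]
        d = L * F
        for i, u in enumerate(config.mlp_units):
            layers.append(Dense(d, u, "relu", rng, name=f"mlp{i}"))
            d = u
        body = Sequential(layers, name="mlp")
        comps = {"mlp": _count(body)}
        width = d
    elif key == "CNN":
        body, width = build_cnn_stream(config.conv, L, F, rng)
        comps = {"cnn_stream": _count(body)}
    elif key in ("LSTM", "GRU"):
        cls = LSTM if key == "LSTM" else GRU
        body = Sequential([cls(F, R, rng=rng, name=key.lower())], name=key)
        comps = {key.lower(): _count(body)}
        width = R
    elif key in ("BiLSTM", "BiGRU"):
        cls = LSTM if key == "BiLSTM" else GRU
        body = Sequential([Bidirectional(
            cls(F, R, rng=rng, name="fw"),
            cls(F, R, reverse=True, rng=rng, name="bw"))], name=key)
        comps = {key.lower(): _count(body)}
        width = 2 * R
    elif key == "ESN":
        rcfg = config.reservoir_for(F)
        esn = EchoState(rcfg, mode=config.esn_mode, name="esn")
        body = Sequential([esn], name="ESN")
        comps = {"esn": _count(body)}
        width = esn.output_width
    elif key in ("CNN-GRU", "CNN-LSTM"):
        convs, _, c = _conv_trunk(config, rng)
        cls = GRU if key == "CNN-GRU" else LSTM
        body = Sequential(convs + [cls(c, R, rng=rng, name="recurrent")],
                          name=key)
        comps = {"cnn": sum(_count(l) for l in convs),
                 "recurrent": _count(body.layers[-1])}
        width = R
    else:  # CNN-ESN
        convs, _, c = _conv_trunk(config, rng)
        rcfg = config.reservoir_for(c)
        esn = EchoState(rcfg, mode=config.esn_mode, name="esn")
        body = Sequential(convs + [esn], name=key)
        comps = {"cnn": sum(_count(l) for l in convs), "esn": 0}
        width = esn.output_width

    head = _head(rng, width, config)
    net = Sequential(body.layers + head.layers, name=key)
    comps["head"] = _count(head)
    return ModelHandle(key, net, config, comps)


def build_model(name: str, config: ModelConfig) -> ModelHandle:
    """Dispatch on any recognised architecture name (baselines + PAR-Net)."""
    return build_baseline(name, config)
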