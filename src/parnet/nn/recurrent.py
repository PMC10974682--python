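"""Recurrent layers: LSTM, GRU, bidirectional wrapper and the echo-state
reservoir layer, all with hand-written backprop through time.

All layers consume (batch, T, in_dim) and emit the final hidden state
(batch, units) — the summary the classification heads read — unless
``return_sequences`` is set.
"""

from __future__ import annotations

import numpy as np

from .core import Layer, Param, glorot
from ..esn import ReservoirConfig, ReservoirParams, init_reservoir

__all__ = ["LSTM", "GRU", "Bidirectional", "EchoState"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Standard LSTM cell (forget-gate bias initialised to 1)."""

    def __init__(self, in_dim: int, units: int, return_sequences: bool = False,
                 reverse: bool = False, rng: np.random.Generator | None = None,
                 name: str = "lstm"):
        rng = rng or np.random.default_rng(0)
        H = units
        self.Wx = Param(glorot(rng, (in_dim, 4 * H), in_dim, H), f"{name}.Wx")
        self.Wh = Param(glorot(rng, (H, 4 * H), H, H), f"{name}.Wh")
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget gate bias
        self.b = Param(b, f"{name}.b")
        self.units = units
        self.return_sequences = return_sequences
        self.reverse = reverse
        self.name = name

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, train=False):
        if self.reverse:
            x = x[:, ::-1, :]
        B, T, _ = x.shape
        H = self.units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        hs = np.empty((B, T, H))
        for t in range(T):
            z = x[:, t, :] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((x[:, t, :], h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._cache = cache
        self._x_shape = x.shape
        if self.return_sequences:
            return hs[:, ::-1, :] if self.reverse else hs
        return h

    def backward(self, grad):
        B, T, _ = self._x_shape
        H = self.units
        if self.return_sequences:
            gs = grad[:, ::-1, :] if self.reverse else grad
            dh_out = gs
            dh = np.zeros((B, H))
        else:
            dh = grad.copy()
            dh_out = None
        dc = np.zeros((B, H))
        dx = np.zeros(self._x_shape)
        for t in range(T - 1, -1, -1):
            if dh_out is not None:
                dh = dh + dh_out[:, t, :]
            xt, h_prev, c_prev, i, f, g, o, c_new, tc = self._cache[t]
            do = dh * tc
            dct = dc + dh * o * (1.0 - tc * tc)
            df = dct * c_prev
            di = dct * g
            dg = dct * i
            dc = dct * f
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g * g),
                do * o * (1 - o),
            ], axis=1)
            self.Wx.grad += xt.T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.value.T
            dh = dz @ self.Wh.value.T
        if self.reverse:
            dx = dx[:, ::-1, :]
        return dx


class GRU(Layer):
    """Gated recurrent unit (reset gate applied to the recurrent term)."""

    def __init__(self, in_dim: int, units: int, return_sequences: bool = False,
                 reverse: bool = False, rng: np.random.Generator | None = None,
                 name: str = "gru"):
        rng = rng or np.random.default_rng(0)
        H = units
        self.Wx = Param(glorot(rng, (in_dim, 3 * H), in_dim, H), f"{name}.Wx")
        self.Wh = Param(glorot(rng, (H, 3 * H), H, H), f"{name}.Wh")
        self.b = Param(np.zeros(3 * H), f"{name}.b")
        self.units = units
        self.return_sequences = return_sequences
        self.reverse = reverse
        self.name = name

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, train=False):
        if self.reverse:
            x = x[:, ::-1, :]
        B, T, _ = x.shape
        H = self.units
        h = np.zeros((B, H))
        cache = []
        hs = np.empty((B, T, H))
        Wxz, Wxr, Wxn = (self.Wx.value[:, :H], self.Wx.value[:, H:2 * H],
                         self.Wx.value[:, 2 * H:])
        Whz, Whr, Whn = (self.Wh.value[:, :H], self.Wh.value[:, H:2 * H],
                         self.Wh.value[:, 2 * H:])
        bz, br, bn = self.b.value[:H], self.b.value[H:2 * H], self.b.value[2 * H:]
        for t in range(T):
            xt = x[:, t, :]
            z = _sigmoid(xt @ Wxz + h @ Whz + bz)
            r = _sigmoid(xt @ Wxr + h @ Whr + br)
            rh = r * h
            n = np.tanh(xt @ Wxn + rh @ Whn + bn)
            h_new = (1.0 - z) * n + z * h
            cache.append((xt, h, z, r, rh, n))
            h = h_new
            hs[:, t, :] = h
        self._cache = cache
        self._x_shape = x.shape
        if self.return_sequences:
            return hs[:, ::-1, :] if self.reverse else hs
        return h

    def backward(self, grad):
        B, T, _ = self._x_shape
        H = self.units
        Wxz, Wxr, Wxn = (self.Wx.value[:, :H], self.Wx.value[:, H:2 * H],
                         self.Wx.value[:, 2 * H:])
        Whz, Whr, Whn = (self.Wh.value[:, :H], self.Wh.value[:, H:2 * H],
                         self.Wh.value[:, 2 * H:])
        if self.return_sequences:
            gs = grad[:, ::-1, :] if self.reverse else grad
            dh = np.zeros((B, H))
            dh_out = gs
        else:
            dh = grad.copy()
            dh_out = None
        dx = np.zeros(self._x_shape)
        for t in range(T - 1, -1, -1):
            if dh_out is not None:
                dh = dh + dh_out[:, t, :]
            xt, h_prev, z, r, rh, n = self._cache[t]
            dn = dh * (1.0 - z)
            dz_gate = dh * (h_prev - n)
            dh_prev = dh * z
            da_n = dn * (1.0 - n * n)
            drh = da_n @ Whn.T
            dr = drh * h_prev
            dh_prev += drh * r
            da_z = dz_gate * z * (1 - z)
            da_r = dr * r * (1 - r)
            dh_prev += da_z @ Whz.T + da_r @ Whr.T
            dx[:, t, :] = da_z @ Wxz.T + da_r @ Wxr.T + da_n @ Wxn.T
            dz_all = np.concatenate([da_z, da_r, da_n], axis=1)
            self.Wx.grad += xt.T @ dz_all
            self.Wh.grad[:, :H] += h_prev.T @ da_z
            self.Wh.grad[:, H:2 * H] += h_prev.T @ da_r
            self.Wh.grad[:, 2 * H:] += rh.T @ da_n
            self.b.grad += dz_all.sum(axis=0)
            dh = dh_prev
        if self.reverse:
            dx = dx[:, ::-1, :]
        return dx


class Bidirectional(Layer):
    """Run a forward and a reversed copy of a recurrent layer and concatenate
    their final states: output width 2 x units."""

    def __init__(self, forward_layer: Layer, backward_layer: Layer,
                 name: str = "bidirectional"):
        if getattr(backward_layer, "reverse", False) is not True:
            raise ValueError("backward_layer must be constructed with reverse=True")
        self.fw = forward_layer
        self.bw = backward_layer
        self.name = name

    def params(self):
        return self.fw.params() + self.bw.params()

    def forward(self, x, train=False):
        yf = self.fw.forward(x, train=train)
        yb = self.bw.forward(x, train=train)
        self._split = yf.shape[-1]
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, grad):
        s = self._split
        return self.fw.backward(grad[..., :s]) + self.bw.backward(grad[..., s:])


class EchoState(Layer):
    """Echo-state reservoir as an in-network temporal stream.

    The reservoir weights are drawn once (see :func:`parnet.esn.init_reservoir`)
    and by default stay fixed: backprop flows through the recurrence to the
    *inputs* (so convolutional layers upstream can train) but does not touch
    W_in or W unless ``trainable_reservoir`` is set.

    Output modes:

    * ``"moments"`` (default) — [mean_t h(t); mean_t h(t)^2], width 2N: the
      extended (squared-states) trajectory summary of reservoir-computing
      practice, which keeps phase-symmetric dynamical signatures linearly
      readable;
    * ``"last"`` — the final state h(T), width N;
    * ``"mean"`` — the state mean over time, width N.
    """

    def __init__(self, config: ReservoirConfig,
                 params: ReservoirParams | None = None,
                 mode: str = "moments", trainable_reservoir: bool = False,
                 name: str = "echo_state"):
        if mode not in ("moments", "last", "mean"):
            raise ValueError("mode must be 'moments', 'last' or 'mean'")
        self.config = config
        self.reservoir = params if params is not None else init_reservoir(config)
        self.W_in = Param(self.reservoir.W_in, f"{name}.W_in",
                          trainable=trainable_reservoir)
        self.W = Param(self.reservoir.W, f"{name}.W",
                       trainable=trainable_reservoir)
        self.mode = mode
        self.trainable_reservoir = trainable_reservoir
        self.name = name

    @property
    def output_width(self) -> int:
        return 2 * self.config.n_units if self.mode == "moments" \
            else self.config.n_units

    def params(self):
        return [self.W_in, self.W] if self.trainable_reservoir else []

    def forward(self, x, train=False):
        B, T, _ = x.shape
        cfg = self.config
        N = cfg.n_units
        h = np.zeros((B, N))
        xs, pres, states = [], [], []
        for t in range(T):
            xa = np.concatenate([np.ones((B, 1)), x[:, t, :]], axis=1)
            a = xa @ self.W_in.value.T + h @ self.W.value.T
            phi = np.tanh(cfg.alpha * a)
            h = ((1.0 - cfg.decay) * h + cfg.decay * phi) / (1.0 + cfg.epsilon)
            xs.append(xa)
            pres.append(phi)
            states.append(h)
        self._cache = (xs, pres, states, x.shape)
        if self.mode == "mean":
            return sum(states) / T
        if self.mode == "moments":
            hbar = sum(states) / T
            h2bar = sum(s * s for s in states) / T
            return np.concatenate([hbar, h2bar], axis=1)
        return h

    def backward(self, grad):
        xs, pres, states, x_shape = self._cache
        cfg = self.config
        B, T, M = x_shape
        N = cfg.n_units
        dx = np.zeros(x_shape)
        scale = 1.0 / (1.0 + cfg.epsilon)
        if self.mode == "last":
            dh = grad.copy()
        else:
            dh = np.zeros((B, N))
        for t in range(T - 1, -1, -1):
            if self.mode == "mean":
                dh = dh + grad / T
            elif self.mode == "moments":
                dh = dh + grad[:, :N] / T \
                    + grad[:, N:] * (2.0 * states[t] / T)
            phi = pres[t]
            dphi = dh * scale * cfg.decay
            da = dphi * (1.0 - phi * phi) * cfg.alpha
            if self.trainable_reservoir:
                hp = states[t - 1] if t > 0 else np.zeros((B, N))
                self.W_in.grad += da.T @ xs[t]
                self.W.grad += da.T @ hp
            dx[:, t, :] = (da @ self.W_in.value)[:, 1:]
            dh = dh * scale * (1.0 - cfg.decay) + da @ self.W.value
        return dx
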