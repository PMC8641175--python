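"""Minimal NumPy neural-network layers with hand-written backprop.

Each layer caches what its backward pass needs during ``forward`` and
exposes ``params``/``grads`` dicts for the optimiser.  Shapes follow the
(batch, channels, height, width) convention for 2-D layers and
(batch, time, features) for recurrent ones.  All layers support float32
(production) and float64 (finite-difference gradient checks).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


def glorot(rng, shape, dtype):
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv2d(Layer):
    """Same-padding, stride-1 2-D convolution via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, dtype=np.float32):
        super().__init__()
        self.k = kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * kernel * kernel
        limit = np.sqrt(6.0 / (fan_in + out_ch))
        self.params["w"] = rng.uniform(
            -limit, limit, size=(out_ch, fan_in)).astype(dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        k, pad = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
        # one big GEMM: (out, C*k*k) @ (C*k*k, B*H*W)
        cols = np.ascontiguousarray(cols.transpose(1, 4, 5, 0, 2, 3))
        cols = cols.reshape(C * k * k, B * H * W)
        self._cols, self._shape = cols, (B, C, H, W)
        y = self.params["w"] @ cols + self.params["b"][:, None]
        return np.ascontiguousarray(
            y.reshape(self.out_ch, B, H, W).transpose(1, 0, 2, 3))

    def backward(self, dy):
        B, C, H, W = self._shape
        k, pad = self.k, self.k // 2
        dy_flat = np.ascontiguousarray(dy.transpose(1, 0, 2, 3))
        dy_flat = dy_flat.reshape(self.out_ch, B * H * W)
        self.grads["w"] = dy_flat @ self._cols.T
        self.grads["b"] = dy_flat.sum(axis=1)
        dcols = self.params["w"].T @ dy_flat  # (C*k*k, B*H*W)
        dcols = dcols.reshape(C, k, k, B, H, W)
        dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += \
                    dcols[:, i, j].transpose(1, 0, 2, 3)
        return dxp[:, :, pad:pad + H, pad:pad + W]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool2d(Layer):
    """Non-overlapping max pool; trailing rows/cols that do not fill a
    full pool cell are cropped (their gradient is zero)."""

    def __init__(self, ph: int, pw: int):
        super().__init__()
        self.ph, self.pw = ph, pw

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        ph, pw = self.ph, self.pw
        H2, W2 = H // ph, W // pw
        self._x, self._shape = x, (B, C, H, W)
        y = x[:, :, :H2 * ph:ph, :W2 * pw:pw].copy()
        for i in range(ph):
            for j in range(pw):
                if i or j:
                    np.maximum(y, x[:, :, i:H2 * ph:ph, j:W2 * pw:pw], out=y)
        self._y = y
        return y

    def backward(self, dy):
        # ties resolved to the first slice in (i, j) scan order
        B, C, H, W = self._shape
        ph, pw = self.ph, self.pw
        H2, W2 = H // ph, W // pw
        dx = np.zeros((B, C, H, W), dtype=dy.dtype)
        claimed = np.zeros(self._y.shape, dtype=bool)
        for i in range(ph):
            for j in range(pw):
                sel = (self._x[:, :, i:H2 * ph:ph, j:W2 * pw:pw] == self._y) \
                    & ~claimed
                dx[:, :, i:H2 * ph:ph, j:W2 * pw:pw] += dy * sel
                claimed |= sel
        return dx


class AvgPool2d(Layer):
    def __init__(self, ph: int, pw: int):
        super().__init__()
        self.ph, self.pw = ph, pw

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        ph, pw = self.ph, self.pw
        H2, W2 = H // ph, W // pw
        self._shape = (B, C, H, W)
        xc = x[:, :, :H2 * ph, :W2 * pw]
        return xc.reshape(B, C, H2, ph, W2, pw).mean(axis=(3, 5))

    def backward(self, dy):
        B, C, H, W = self._shape
        ph, pw = self.ph, self.pw
        H2, W2 = H // ph, W // pw
        dxc = np.repeat(np.repeat(dy, ph, axis=2), pw, axis=3) / (ph * pw)
        dx = np.zeros((B, C, H, W), dtype=dy.dtype)
        dx[:, :, :H2 * ph, :W2 * pw] = dxc
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        B, C, H, W = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (H * W),
                               self._shape).astype(dy.dtype).copy()


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng, dtype=np.float32):
        super().__init__()
        self.params["w"] = glorot(rng, (d_in, d_out), dtype)
        self.params["b"] = np.zeros(d_out, dtype=dtype)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy):
        self.grads["w"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["w"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class SEBlock(Layer):
    """Squeeze-and-excitation channel re-weighting.

    Global average pool per channel, a bottleneck of two 1x1 transforms
    (reduce by ``reduction``, ReLU, expand, sigmoid), then channel-wise
    scaling of the input.
    """

    def __init__(self, channels: int, reduction: int, rng, dtype=np.float32):
        super().__init__()
        mid = max(1, channels // reduction)
        self.params["w1"] = glorot(rng, (channels, mid), dtype)
        self.params["b1"] = np.zeros(mid, dtype=dtype)
        self.params["w2"] = glorot(rng, (mid, channels), dtype)
        self.params["b2"] = np.zeros(channels, dtype=dtype)

    def forward(self, x, train=False):
        self._x = x
        s = x.mean(axis=(2, 3))  # (B, C)
        z = s @ self.params["w1"] + self.params["b1"]
        zr = np.maximum(z, 0.0)
        g = 1.0 / (1.0 + np.exp(-(zr @ self.params["w2"] + self.params["b2"])))
        self._s, self._z, self._zr, self._g = s, z, zr, g
        return x * g[:, :, None, None]

    def backward(self, dy):
        x, g = self._x, self._g
        B, C, H, W = x.shape
        dx = dy * g[:, :, None, None]
        dg = (dy * x).sum(axis=(2, 3))
        dpre2 = dg * g * (1.0 - g)
        self.grads["w2"] = self._zr.T @ dpre2
        self.grads["b2"] = dpre2.sum(axis=0)
        dzr = dpre2 @ self.params["w2"].T
        dz = dzr * (self._z > 0)
        self.grads["w1"] = self._s.T @ dz
        self.grads["b1"] = dz.sum(axis=0)
        ds = dz @ self.params["w1"].T
        dx += ds[:, :, None, None] / (H * W)
        return dx


class LSTM(Layer):
    """Single-direction LSTM over (batch, time, features).

    One cell step computes, with sigmoid gates and tanh activations:
      I_t = sigmoid(W_I x_t + U_I h_{t-1} + b_I)
      F_t = sigmoid(W_F x_t + U_F h_{t-1} + b_F)
      O_t = sigmoid(W_O x_t + U_O h_{t-1} + b_O)
      C_t = F_t * C_{t-1} + I_t * tanh(W_C x_t + U_C h_{t-1} + b_C)
      h_t = O_t * tanh(C_t)
    Gate blocks are stored concatenated in order [I, F, O, C].
    """

    def __init__(self, d_in: int, units: int, rng, dtype=np.float32):
        super().__init__()
        self.units = units
        self.params["wx"] = glorot(rng, (d_in, 4 * units), dtype)
        self.params["wh"] = glorot(rng, (units, 4 * units), dtype)
        b = np.zeros(4 * units, dtype=dtype)
        b[units:2 * units] = 1.0  # forget-gate bias
        self.params["b"] = b

    def step(self, x_t, h_prev, c_prev):
        """One cell update; returns (h, c, cache)."""
        u = self.units
        z = x_t @ self.params["wx"] + h_prev @ self.params["wh"] + self.params["b"]
        i = 1.0 / (1.0 + np.exp(-z[:, :u]))
        f = 1.0 / (1.0 + np.exp(-z[:, u:2 * u]))
        o = 1.0 / (1.0 + np.exp(-z[:, 2 * u:3 * u]))
        g = np.tanh(z[:, 3 * u:])
        c = f * c_prev + i * g
        hc = np.tanh(c)
        h = o * hc
        return h, c, (x_t, h_prev, c_prev, i, f, o, g, hc)

    def forward(self, x, train=False):
        B, T, D = x.shape
        u = self.units
        h = np.zeros((B, u), dtype=x.dtype)
        c = np.zeros((B, u), dtype=x.dtype)
        self._caches = []
        out = np.empty((B, T, u), dtype=x.dtype)
        for t in range(T):
            h, c, cache = self.step(x[:, t], h, c)
            self._caches.append(cache)
            out[:, t] = h
        self._in_shape = (B, T, D)
        return out

    def backward(self, dy):
        B, T, D = self._in_shape
        u = self.units
        wx, wh = self.params["wx"], self.params["wh"]
        dwx = np.zeros_like(wx)
        dwh = np.zeros_like(wh)
        db = np.zeros_like(self.params["b"])
        dx = np.empty((B, T, D), dtype=dy.dtype)
        dh_next = np.zeros((B, u), dtype=dy.dtype)
        dc_next = np.zeros((B, u), dtype=dy.dtype)
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, o, g, hc = self._caches[t]
            dh = dy[:, t] + dh_next
            do = dh * hc
            dc = dh * o * (1.0 - hc * hc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 do * o * (1 - o), dg * (1 - g * g)], axis=1)
            dwx += x_t.T @ dz
            dwh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ wx.T
            dh_next = dz @ wh.T
        self.grads["wx"], self.grads["wh"], self.grads["b"] = dwx, dwh, db
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM: forward and reversed passes concatenated."""

    def __init__(self, d_in: int, units: int, rng, dtype=np.float32):
        super().__init__()
        self.fwd = LSTM(d_in, units, rng, dtype)
        self.bwd = LSTM(d_in, units, rng, dtype)

    @property
    def children(self):
        return {"fwd": self.fwd, "bwd": self.bwd}

    def forward(self, x, train=False):
        yf = self.fwd.forward(x, train)
        yb = self.bwd.forward(x[:, ::-1], train)[:, ::-1]
        return np.concatenate([yf, yb], axis=2)

    def backward(self, dy):
        u = self.fwd.units
        dxf = self.fwd.backward(dy[:, :, :u])
        dxb = self.bwd.backward(dy[:, ::-1, u:])[:, ::-1]
        return dxf + dxb
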