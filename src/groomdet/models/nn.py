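"""Minimal numpy neural-network engine: layers, backprop, AMSGrad.

Channels-last layout throughout: video inputs are (N, D, H, W, C).
Each layer implements ``forward(x, training)`` and ``backward(dy)``;
gradients accumulate into per-parameter ``grad`` buffers consumed by the
optimizer.  Gradient correctness is covered by finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3D(Layer):
    """'Same'-padded 3-D convolution with kernel (kd, kh, kw), stride 1.

    A (1, 3, 3) kernel degenerates to a per-frame 2-D convolution, which is
    how the recurrent architecture shares its 2-D feature extractor across
    time.
    """

    def __init__(self, cin: int, cout: int, kernel=(3, 3, 3), rng=None, name="conv"):
        self.cin, self.cout, self.kernel = cin, cout, tuple(kernel)
        kd, kh, kw = self.kernel
        fan_in = kd * kh * kw * cin
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cout))
        self.w = Param(f"{name}.w", w.astype(np.float32))
        self.b = Param(f"{name}.b", np.zeros(cout, dtype=np.float32))
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        n, d, h, wd, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        kd, kh, kw = self.kernel
        pad = (kd // 2, kh // 2, kw // 2)
        xp = np.pad(x, ((0, 0), (pad[0],) * 2, (pad[1],) * 2, (pad[2],) * 2, (0, 0)))
        # windows: (n, d, h, w, c, kd, kh, kw) -> (n*d*h*w, kd*kh*kw*c)
        win = sliding_window_view(xp, self.kernel, axis=(1, 2, 3))
        cols = win.transpose(0, 1, 2, 3, 5, 6, 7, 4).reshape(n * d * h * wd, -1)
        cols = np.ascontiguousarray(cols, dtype=self.w.value.dtype)
        y = cols @ self.w.value + self.b.value
        self._cols, self._xshape, self._pad = cols, x.shape, pad
        return y.reshape(n, d, h, wd, self.cout)

    def backward(self, dy):
        n, d, h, wd, _ = self._xshape
        kd, kh, kw = self.kernel
        dmat = dy.reshape(-1, self.cout)
        self.w.grad += self._cols.T @ dmat
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.w.value.T).reshape(n, d, h, wd, kd, kh, kw, self.cin)
        pd, ph, pw = self._pad
        dxp = np.zeros((n, d + 2 * pd, h + 2 * ph, wd + 2 * pw, self.cin),
                       dtype=dy.dtype)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    dxp[:, i:i + d, j:j + h, k:k + wd, :] += dcols[:, :, :, :, i, j, k, :]
        return dxp[:, pd:pd + d, ph:ph + h, pw:pw + wd, :]


class MaxPool3D(Layer):
    """Max pooling with pool = stride; trailing remainders are cropped."""

    def __init__(self, pool=(2, 2, 2)):
        self.pool = tuple(pool)

    def forward(self, x, training=False):
        n, d, h, w, c = x.shape
        pd, ph, pw = self.pool
        dc, hc, wc = d // pd * pd, h // ph * ph, w // pw * pw
        if dc == 0 or hc == 0 or wc == 0:
            raise ValueError(f"input {x.shape} too small for pool {self.pool}")
        xc = x[:, :dc, :hc, :wc, :]
        win = xc.reshape(n, dc // pd, pd, hc // ph, ph, wc // pw, pw, c)
        win = win.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(
            n, dc // pd, hc // ph, wc // pw, c, pd * ph * pw)
        self._arg = np.argmax(win, axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, d, h, w, c = self._xshape
        pd, ph, pw = self.pool
        dc, hc, wc = d // pd * pd, h // ph * ph, w // pw * pw
        dwin = np.zeros(dy.shape + (pd * ph * pw,), dtype=dy.dtype)
        np.put_along_axis(dwin, self._arg[..., None], dy[..., None], axis=-1)
        dwin = dwin.reshape(n, dc // pd, hc // ph, wc // pw, c, pd, ph, pw)
        dxc = dwin.transpose(0, 1, 5, 2, 6, 3, 7, 4).reshape(n, dc, hc, wc, c)
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        dx[:, :dc, :hc, :wc, :] = dxc
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class FlattenFrames(Layer):
    """(N, T, H, W, C) -> (N, T, H*W*C): per-timestep feature vectors."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], x.shape[1], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng=None, name="dense"):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, cout))
        self.w = Param(f"{name}.w", w.astype(np.float32))
        self.b = Param(f"{name}.b", np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class LSTM(Layer):
    """Single-direction LSTM over (N, T, F); gates ordered i, f, g, o.

    Glorot-uniform kernels, orthogonal-free recurrent init (also Glorot),
    forget-gate bias 1.  Full backpropagation through time.
    """

    def __init__(self, cin: int, units: int, return_sequences: bool = False,
                 rng=None, name="lstm"):
        rng = rng or np.random.default_rng()
        self.units = units
        self.return_sequences = return_sequences
        lim_w = np.sqrt(6.0 / (cin + 4 * units))
        lim_u = np.sqrt(6.0 / (units + 4 * units))
        self.w = Param(f"{name}.w", rng.uniform(-lim_w, lim_w, (cin, 4 * units)).astype(np.float32))
        self.u = Param(f"{name}.u", rng.uniform(-lim_u, lim_u, (units, 4 * units)).astype(np.float32))
        b = np.zeros(4 * units, dtype=np.float32)
        b[units:2 * units] = 1.0  # forget bias
        self.b = Param(f"{name}.b", b)

    def params(self):
        return [self.w, self.u, self.b]

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    def forward(self, x, training=False):
        n, t, f = x.shape
        u = self.units
        h = np.zeros((n, u), dtype=x.dtype)
        c = np.zeros((n, u), dtype=x.dtype)
        self._cache = []
        hs = np.empty((n, t, u), dtype=x.dtype)
        for step in range(t):
            z = x[:, step, :] @ self.w.value + h @ self.u.value + self.b.value
            i = self._sigmoid(z[:, :u])
            fg = self._sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = self._sigmoid(z[:, 3 * u:])
            c_new = fg * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((x[:, step, :], h, c, i, fg, g, o, tanh_c))
            h, c = h_new, c_new
            hs[:, step, :] = h
        self._x_shape = x.shape
        self._hs = hs
        return hs if self.return_sequences else hs[:, -1, :]

    def backward(self, dy):
        n, t, f = self._x_shape
        u = self.units
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        dh_next = np.zeros((n, u), dtype=dy.dtype)
        dc_next = np.zeros((n, u), dtype=dy.dtype)
        for step in reversed(range(t)):
            x_t, h_prev, c_prev, i, fg, g, o, tanh_c = self._cache[step]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dy[:, step, :]
            elif step == t - 1:
                dh += dy
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            dfg = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                dfg * fg * (1 - fg),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            self.w.grad += x_t.T @ dz
            self.u.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, step, :] = dz @ self.w.value.T
            dh_next = dz @ self.u.value.T
            dc_next = dc * fg
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    eps = np.finfo(probs.dtype).tiny
    loss = float(-(onehot * np.log(probs + eps)).sum(axis=-1).mean())
    dlogits = (probs - onehot) / logits.shape[0]
    return loss, dlogits.astype(logits.dtype)


class AMSGrad:
    """Adam with the non-decreasing second-moment correction (AMSGrad)."""

    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.vhat = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v, vh in zip(self.params, self.m, self.v, self.vhat):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            np.maximum(vh, v, out=vh)
            mhat = m / bias1
            vhhat = vh / bias2
            p.value -= self.lr * mhat / (np.sqrt(vhhat) + self.eps)
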