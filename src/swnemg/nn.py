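"""Minimal numpy layer framework with manual backpropagation.

Implements exactly the layers the sequence classifier needs -- layer
normalization, 1-D convolution, anti-aliased (blur) pooling, LSTM, dropout,
gradient reversal, linear -- each as a stateful object caching its forward
activations for a single subsequent backward pass, plus an Adam optimizer.
Gradients are checked against central finite differences in the test suite.

Each layer draws its initial weights from an rng passed at construction, so
model builders can key rng streams per layer and keep initializations stable
when optional heads are added or removed.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy.special import expit

__all__ = [
    "Param",
    "Layer",
    "LayerNorm",
    "ReLU",
    "Dropout",
    "Conv1d",
    "BlurPool1d",
    "GlobalAvgPool1d",
    "Linear",
    "LSTM",
    "GradReversal",
    "Sequential",
    "Adam",
    "default_dtype",
]

#: Default parameter/compute dtype.  float32 roughly halves training time;
#: gradient-check tests switch to float64 via :func:`default_dtype` because
#: central finite differences need ~1e-10 arithmetic headroom.
DTYPE = np.float32


@contextmanager
def default_dtype(dtype):
    """Temporarily change the dtype used for newly created parameters."""
    global DTYPE
    old = DTYPE
    DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DTYPE = old


class Param:
    __slots__ = ("v", "g", "name")

    def __init__(self, v: np.ndarray, name: str = ""):
        self.v = np.asarray(v, dtype=DTYPE)
        self.g = np.zeros_like(self.v)
        self.name = name


class Layer:
    train = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class LayerNorm(Layer):
    """Normalize over the trailing ``len(shape)`` axes with learnable affine."""

    def __init__(self, shape: tuple[int, ...] | int, eps: float = 1e-5):
        if isinstance(shape, int):
            shape = (shape,)
        self.shape = shape
        self.eps = eps
        self.gamma = Param(np.ones(shape), "ln.gamma")
        self.beta = Param(np.zeros(shape), "ln.beta")
        self.axes = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        nd = len(self.shape)
        if x.shape[-nd:] != self.shape:
            raise ValueError(f"LayerNorm expects trailing shape {self.shape}, got {x.shape}")
        self.axes = tuple(range(x.ndim - nd, x.ndim))
        mu = x.mean(axis=self.axes, keepdims=True)
        var = x.var(axis=self.axes, keepdims=True)
        self.inv = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mu) * self.inv
        return self.gamma.v * self.xhat + self.beta.v

    def backward(self, gy):
        lead = tuple(range(gy.ndim - len(self.shape)))
        self.gamma.g += (gy * self.xhat).sum(axis=lead)
        self.beta.g += gy.sum(axis=lead)
        dxhat = gy * self.gamma.v
        m1 = dxhat.mean(axis=self.axes, keepdims=True)
        m2 = (dxhat * self.xhat).mean(axis=self.axes, keepdims=True)
        return self.inv * (dxhat - m1 - self.xhat * m2)


class ReLU(Layer):
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, gy):
        return gy * self.mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x):
        if not self.train or self.p == 0:
            self.mask = None
            return x
        u = self.rng.random(x.shape, dtype=np.float32)
        self.mask = (u >= self.p).astype(x.dtype) / x.dtype.type(1.0 - self.p)
        return x * self.mask

    def backward(self, gy):
        return gy if self.mask is None else gy * self.mask


class Conv1d(Layer):
    """Channel-to-channel 1-D convolution, stride 1, symmetric zero padding.

    Computed as ``kernel`` shifted channel-mixing matrix products
    ``y = sum_j W[:, :, j] @ x_padded[..., j : j + L_out]`` in a
    channels-leading ``(C, B*L)`` layout, so every product is one large GEMM
    and no im2col buffer is materialized.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, padding: int,
                 rng: np.random.Generator):
        k = 1.0 / np.sqrt(c_in * kernel)
        self.w = Param(rng.uniform(-k, k, size=(c_out, c_in, kernel)), "conv.w")
        self.b = Param(rng.uniform(-k, k, size=c_out), "conv.b")
        self.kernel = kernel
        self.padding = padding

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        b, c, l = x.shape
        p, k = self.padding, self.kernel
        co = self.w.v.shape[0]
        lp = l + 2 * p
        lo = lp - k + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        xt = np.ascontiguousarray(xp.transpose(1, 0, 2)).reshape(c, b * lp)
        self.xt = xt
        self.in_shape = x.shape
        acc = np.zeros((co, b, lo), dtype=x.dtype)
        for j in range(k):
            full = (self.w.v[:, :, j] @ xt).reshape(co, b, lp)
            acc += full[:, :, j : j + lo]
        acc += self.b.v[:, None, None]
        return np.ascontiguousarray(acc.transpose(1, 0, 2))

    def backward(self, gy):
        b, c, l = self.in_shape
        p, k = self.padding, self.kernel
        co, lo = gy.shape[1], gy.shape[2]
        lp = l + 2 * p
        gyt = np.ascontiguousarray(gy.transpose(1, 0, 2)).reshape(co, b * lo)
        xt3 = self.xt.reshape(c, b, lp)
        dxt = np.zeros((c, b, lp), dtype=gy.dtype)
        for j in range(k):
            seg = np.ascontiguousarray(xt3[:, :, j : j + lo]).reshape(c, b * lo)
            self.w.g[:, :, j] += gyt @ seg.T
            dxt[:, :, j : j + lo] += (self.w.v[:, :, j].T @ gyt).reshape(c, b, lo)
        self.b.g += gyt.sum(axis=1)
        dxp = dxt.transpose(1, 0, 2)
        return np.ascontiguousarray(dxp[:, :, p : p + l] if p else dxp)


class BlurPool1d(Layer):
    """Anti-aliased downsampling: fixed binomial [1,2,1]/4 depthwise filter,
    stride 2, padding 1."""

    KERNEL = np.array([0.25, 0.5, 0.25])

    def forward(self, x):
        b, c, l = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1)))
        view = np.lib.stride_tricks.sliding_window_view(xp, 3, axis=2)[:, :, ::2, :]
        self.in_shape = x.shape
        self.lo = view.shape[2]
        return view @ self.KERNEL.astype(x.dtype)

    def backward(self, gy):
        b, c, l = self.in_shape
        dxp = np.zeros((b, c, l + 2), dtype=gy.dtype)
        for j in range(3):
            dxp[:, :, j : j + 2 * self.lo : 2] += gy.dtype.type(self.KERNEL[j]) * gy
        return dxp[:, :, 1 : 1 + l]

    @staticmethod
    def out_len(l: int) -> int:
        return (l + 2 - 3) // 2 + 1


class GlobalAvgPool1d(Layer):
    """Mean over the trailing (intra-frame time) axis."""

    def forward(self, x):
        self.l = x.shape[-1]
        return x.mean(axis=-1)

    def backward(self, gy):
        return np.repeat(gy[..., None], self.l, axis=-1) / self.l


class Linear(Layer):
    """Affine map.  ``init="zero"`` starts weights and bias at zero, useful
    for output heads so that initial predictions are uniform and early
    optimizer steps need not unlearn random logits."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "uniform"):
        if init == "zero":
            self.w = Param(np.zeros((n_in, n_out)), "linear.w")
            self.b = Param(np.zeros(n_out), "linear.b")
        else:
            k = 1.0 / np.sqrt(n_in)
            self.w = Param(rng.uniform(-k, k, size=(n_in, n_out)), "linear.w")
            self.b = Param(rng.uniform(-k, k, size=n_out), "linear.b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self.x = x
        return x @ self.w.v + self.b.v

    def backward(self, gy):
        lead = self.x.reshape(-1, self.x.shape[-1])
        g = gy.reshape(-1, gy.shape[-1])
        self.w.g += lead.T @ g
        self.b.g += g.sum(axis=0)
        return gy @ self.w.v.T


def _sigmoid(z):
    return expit(z)


class LSTM(Layer):
    """Single LSTM layer over (batch, time, features); hidden size = input size
    unless given.  Gate order i, f, g, o; zero initial state.

    The input projection ``x @ Wx`` for all time steps is computed as one
    matrix product before the recurrence; only the ``h @ Wh`` term stays in
    the per-step loop.  Backward accumulates per-step gate sensitivities and
    forms the weight gradients as two flat matrix products afterwards.
    """

    def __init__(self, n_in: int, hidden: int | None, rng: np.random.Generator):
        h = n_in if hidden is None else hidden
        k = 1.0 / np.sqrt(h)
        self.h = h
        self.wx = Param(rng.uniform(-k, k, size=(n_in, 4 * h)), "lstm.wx")
        self.wh = Param(rng.uniform(-k, k, size=(h, 4 * h)), "lstm.wh")
        b0 = rng.uniform(-k, k, size=4 * h)
        b0[h : 2 * h] += 1.0  # forget-gate bias toward remembering at init
        self.b = Param(b0, "lstm.b")

    def params(self):
        return [self.wx, self.wh, self.b]

    def forward(self, x):
        b, t, n_in = x.shape
        h = self.h
        self.x = x
        zx = (x.reshape(b * t, n_in) @ self.wx.v + self.b.v).reshape(b, t, 4 * h)
        gates = np.empty((b, t, 4 * h), dtype=x.dtype)
        cs = np.empty((b, t, h), dtype=x.dtype)
        tcs = np.empty((b, t, h), dtype=x.dtype)
        hs = np.empty((b, t, h), dtype=x.dtype)
        h_t = np.zeros((b, h), dtype=x.dtype)
        c_t = np.zeros((b, h), dtype=x.dtype)
        wh = self.wh.v
        for step in range(t):
            z = zx[:, step] + h_t @ wh
            i = expit(z[:, :h])
            f = expit(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = expit(z[:, 3 * h :])
            c_t = f * c_t + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            gates[:, step, :h] = i
            gates[:, step, h : 2 * h] = f
            gates[:, step, 2 * h : 3 * h] = g
            gates[:, step, 3 * h :] = o
            cs[:, step] = c_t
            tcs[:, step] = tc
            hs[:, step] = h_t
        self.gates, self.cs, self.tcs, self.hs = gates, cs, tcs, hs
        return hs

    def backward(self, gy):
        b, t, _ = gy.shape
        h = self.h
        gates, cs, tcs = self.gates, self.cs, self.tcs
        dz_all = np.empty((b, t, 4 * h), dtype=gy.dtype)
        dh_next = np.zeros((b, h), dtype=gy.dtype)
        dc_next = np.zeros((b, h), dtype=gy.dtype)
        zeros_c = np.zeros((b, h), dtype=gy.dtype)
        whT = self.wh.v.T
        for step in range(t - 1, -1, -1):
            i = gates[:, step, :h]
            f = gates[:, step, h : 2 * h]
            g = gates[:, step, 2 * h : 3 * h]
            o = gates[:, step, 3 * h :]
            tc = tcs[:, step]
            c_prev = cs[:, step - 1] if step > 0 else zeros_c
            dh = gy[:, step] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            dc_next = dc * f
            dz = dz_all[:, step]
            dz[:, :h] = dc * g * i * (1 - i)
            dz[:, h : 2 * h] = dc * c_prev * f * (1 - f)
            dz[:, 2 * h : 3 * h] = dc * i * (1 - g * g)
            dz[:, 3 * h :] = do * o * (1 - o)
            dh_next = dz @ whT
        dz_flat = dz_all.reshape(b * t, 4 * h)
        x_flat = self.x.reshape(b * t, -1)
        self.wx.g += x_flat.T @ dz_flat
        h_prev = np.concatenate(
            [np.zeros((b, 1, h), dtype=gy.dtype), self.hs[:, :-1]], axis=1
        )
        self.wh.g += h_prev.reshape(b * t, h).T @ dz_flat
        self.b.g += dz_flat.sum(axis=0)
        return (dz_flat @ self.wx.v.T).reshape(self.x.shape)


class GradReversal(Layer):
    """Identity forward; multiplies backward sensitivities by -lambda."""

    def __init__(self, lam: float = 1.0):
        if not np.isfinite(lam):
            raise ValueError("lambda must be finite")
        self.lam = lam

    def forward(self, x):
        return x

    def backward(self, gy):
        return -self.lam * gy


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy

    def set_train(self, train: bool):
        for l in self.layers:
            l.train = train
            if isinstance(l, Sequential):
                l.set_train(train)


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.g
            v *= self.b2
            v += (1 - self.b2) * p.g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.v -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
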