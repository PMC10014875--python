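"""Minimal CPU neural-network kernels (conv / pool / dense / dropout).

Implemented directly on numpy: convolutions run as im2col windows fed to
BLAS ``tensordot``, which is the fastest portable route on a plain CPU.
All arithmetic is float32. Layers follow the usual forward/backward
protocol and hold their parameters and gradients; the Adam optimizer
updates them in place.

Only what the frame classifier needs is implemented: 3x3 valid
convolution, 2x2 max pooling, dense layers, ReLU, inverted dropout, and
softmax / sigmoid cross-entropy with per-sample weights.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _init_weights(rng: np.random.Generator, shape: tuple[int, ...],
                  fan_in: int, fan_out: int, kind: str = "he"):
    """He-normal for ReLU-fed layers, Glorot-uniform for linear heads."""
    if kind == "he":
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv3x3(Layer):
    """3x3 convolution, valid padding, stride 1.

    Runs as nine shifted GEMMs rather than one big im2col product: same
    arithmetic, but the temporaries stay a small multiple of the
    activation size, which keeps the layer memory- and cache-friendly.
    """

    def __init__(self, in_c: int, out_c: int, rng: np.random.Generator,
                 skip_input_grad: bool = False, init: str = "he"):
        super().__init__()
        self.W = _init_weights(rng, (3, 3, in_c, out_c), 9 * in_c, 9 * out_c, init)
        self.b = np.zeros(out_c, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.skip_input_grad = skip_input_grad
        self._x: np.ndarray | None = None

    def forward(self, x, train):
        if train:
            self._x = x
        win = sliding_window_view(x, (3, 3), axis=(1, 2))  # B,H',W',C,3,3
        y = np.tensordot(win, self.W, axes=([4, 5, 3], [0, 1, 2]))
        return (y + self.b).astype(np.float32, copy=False)

    def backward(self, dout):
        x = self._x
        b, h, w, c = x.shape
        ho, wo = h - 2, w - 2
        dflat = dout.reshape(-1, dout.shape[3])
        dx = None if self.skip_input_grad else np.zeros_like(x)
        for p in range(3):
            for q in range(3):
                xs = np.ascontiguousarray(x[:, p : p + ho, q : q + wo, :])
                self.grads[0][p, q] = xs.reshape(-1, c).T @ dflat
                if dx is not None:
                    dx[:, p : p + ho, q : q + wo, :] += (
                        dflat @ self.W[p, q].T
                    ).reshape(b, ho, wo, c)
        self.grads[1][...] = dflat.sum(axis=0)
        self._x = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped.

    Works on four strided window views to avoid large transposes; the
    gradient goes to the first maximum in each window (row-major), so
    ties never duplicate gradient mass.
    """

    @staticmethod
    def _windows(x, h2, w2):
        return (
            x[:, 0 : 2 * h2 : 2, 0 : 2 * w2 : 2],
            x[:, 0 : 2 * h2 : 2, 1 : 2 * w2 : 2],
            x[:, 1 : 2 * h2 : 2, 0 : 2 * w2 : 2],
            x[:, 1 : 2 * h2 : 2, 1 : 2 * w2 : 2],
        )

    def forward(self, x, train):
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        a0, a1, a2, a3 = self._windows(x, h2, w2)
        y = np.maximum(np.maximum(a0, a1), np.maximum(a2, a3))
        if train:
            self._shape = x.shape
            arg = np.full((b, h2, w2, c), 3, dtype=np.int8)
            arg[a2 == y] = 2
            arg[a1 == y] = 1
            arg[a0 == y] = 0
            self._arg = arg
        return y

    def backward(self, dout):
        b, h, w, c = self._shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros((b, h, w, c), dtype=np.float32)
        slots = self._windows(dx, h2, w2)
        for k, slot in enumerate(slots):
            np.copyto(slot, dout, where=self._arg == k)
        self._arg = None
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        y = np.maximum(x, 0)
        if train:
            self._y = y  # y > 0 iff x > 0, so the output doubles as the mask
        return y

    def backward(self, dout):
        dout[self._y <= 0] = 0.0
        self._y = None
        return dout


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "he"):
        super().__init__()
        self.W = _init_weights(rng, (n_in, n_out), n_in, n_out, init)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(np.float32)
        return x * self._mask / (1.0 - self.rate)

    def backward(self, dout):
        if self.rate <= 0:
            return dout
        dx = dout * self._mask / (1.0 - self.rate)
        self._mask = None
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
            if dout is None:
                break

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


class Adam:
    """Adaptive moment estimation with a mutable learning rate."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self._buf = [np.empty_like(p) for p in params]  # temporary-free updates
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = np.float32(1.0 - self.beta1**self.t)
        b2t = np.float32(1.0 - self.beta2**self.t)
        for p, g, m, v, buf in zip(self.params, grads, self.m, self.v, self._buf):
            m *= np.float32(self.beta1)
            np.multiply(g, np.float32(1.0 - self.beta1), out=buf)
            m += buf
            v *= np.float32(self.beta2)
            np.multiply(g, g, out=buf)
            buf *= np.float32(1.0 - self.beta2)
            v += buf
            np.divide(v, b2t, out=buf)
            np.sqrt(buf, out=buf)
            buf += np.float32(self.eps)
            np.divide(m, buf, out=buf)
            buf *= np.float32(self.lr / b1t)
            p -= buf


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray,
                 sample_weight: np.ndarray | None = None):
    """Weighted categorical cross-entropy; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    ce = -np.log(p[np.arange(n), y] + eps)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=np.float64)
    loss = float(np.mean(w * ce))
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / n)[:, None]
    return loss, dlogits.astype(np.float32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def binary_xent(logits: np.ndarray, y: np.ndarray,
                sample_weight: np.ndarray | None = None):
    """Weighted binary cross-entropy on a single logit column."""
    n = logits.shape[0]
    p = sigmoid(logits[:, 0].astype(np.float64))
    eps = 1e-12
    yf = y.astype(np.float64)
    ce = -(yf * np.log(p + eps) + (1 - yf) * np.log(1 - p + eps))
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=np.float64)
    loss = float(np.mean(w * ce))
    dlogits = ((p - yf) * w / n)[:, None]
    return loss, dlogits.astype(np.float32)
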