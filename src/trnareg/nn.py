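"""A small, fully deterministic numpy neural-network engine.

Implements exactly the pieces the tRNet architecture needs — dilated 1D
convolutions with same padding, rectified linear units, global max
pooling, dense layers, softmax / sigmoid cross-entropy losses and the
Adam optimizer — with hand-written backward passes, including gradients
with respect to the input sequence (required for attribution).  All
parameters are float32; all randomness flows through a caller-supplied
``numpy.random.Generator``, so training is bit-reproducible on one
platform.

Convolutions are evaluated as a sum of ``width`` dense matmuls over the
dilated taps, which keeps both directions of the pass inside BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "ReLU",
    "GlobalMaxPool",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "sigmoid",
    "softmax_cross_entropy",
    "sigmoid_cross_entropy",
]

DTYPE = np.float32


class Layer:
    trainable: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1D(Layer):
    """1D convolution over (N, L, C_in) with dilation and same padding.

    With an even width the extra pad goes on the right, so output length
    always equals input length.
    """

    def __init__(self, c_in: int, c_out: int, width: int, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (width * c_in))
        self.w = (rng.standard_normal((width, c_in, c_out)) * scale).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dilation = dilation
        span = (width - 1) * dilation
        self.pad_left = span // 2
        self.pad_right = span - self.pad_left
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    @property
    def width(self) -> int:
        return self.w.shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, L, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        self._xp = xp
        self._L = L
        y = np.broadcast_to(self.b, (n, L, self.b.shape[0])).copy()
        d = self.dilation
        for j in range(self.width):
            y += xp[:, j * d : j * d + L, :] @ self.w[j]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, L, d = self._xp, self._L, self.dilation
        n = dy.shape[0]
        c_out = self.b.shape[0]
        dy2 = dy.reshape(-1, c_out)
        self.db = dy.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for j in range(self.width):
            seg = xp[:, j * d : j * d + L, :].reshape(-1, xp.shape[2])
            self.dw[j] = seg.T @ dy2
            dxp[:, j * d : j * d + L, :] += dy @ self.w[j].T
        return dxp[:, self.pad_left : self.pad_left + L, :]

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class GlobalMaxPool(Layer):
    """(N, L, C) -> (N, C); gradient routes to the argmax position."""

    def forward(self, x):
        self._idx = x.argmax(axis=1)  # (N, C)
        self._shape = x.shape
        return np.take_along_axis(x, self._idx[:, None, :], axis=1)[:, 0, :]

    def backward(self, dy):
        dx = np.zeros(self._shape, dtype=dy.dtype)
        np.put_along_axis(dx, self._idx[:, None, :], dy[:, None, :], axis=1)
        return dx


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_in, c_out)) * scale).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Residual(Layer):
    """Skip connection around an inner stack: y = x + g(x).

    Parameter-free in itself; exposes the inner layers' parameters.  The
    inner output must match the input shape.
    """

    def __init__(self, inner: list[Layer]):
        self.inner = inner

    def forward(self, x):
        y = x
        for layer in self.inner:
            y = layer.forward(y)
        return x + y

    def backward(self, dy):
        d = dy
        for layer in reversed(self.inner):
            d = layer.backward(d)
        return dy + d

    def params(self):
        return [p for l in self.inner for p in l.params()]

    def grads(self):
        return [g for l in self.inner for g in l.grads()]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def atomic_layers(self):
        """Leaf layers, with residual blocks flattened (freezing and the
        optimizer act at this granularity)."""
        for layer in self.layers:
            if isinstance(layer, Residual):
                yield from layer.inner
            else:
                yield layer

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate; returns the gradient w.r.t. the network input."""
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def param_count(self) -> int:
        return sum(int(p.size) for layer in self.layers for p in layer.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params()]
        if len(flat) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(flat, weights):
            p[...] = w


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy for integer labels; returns
    (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-30)).mean()
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    return float(loss), (d / n).astype(DTYPE)


def sigmoid_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy for 0/1 labels on a 1-unit head."""
    z = logits.ravel().astype(np.float64)
    y = y.astype(np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    d = (sigmoid(z) - y) / len(z)
    return float(loss.mean()), d.reshape(logits.shape).astype(DTYPE)


class Adam:
    """Adam with per-parameter state; frozen layers are skipped entirely."""

    def __init__(self, model: Sequential, lr: float = 0.00025,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer in self.model.atomic_layers():
            if not layer.trainable:
                continue
            for p, g in zip(layer.params(), layer.grads()):
                key = id(p)
                if key not in self.m:
                    self.m[key] = np.zeros_like(p, dtype=np.float64)
                    self.v[key] = np.zeros_like(p, dtype=np.float64)
                m = self.m[key] = b1 * self.m[key] + (1 - b1) * g
                v = self.v[key] = b2 * self.v[key] + (1 - b2) * g.astype(np.float64) ** 2
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
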