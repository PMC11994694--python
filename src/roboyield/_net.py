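"""A compact numpy CNN: the layers, backprop and Adam optimizer behind the
point-proposal counting network and the yield regressor.

Layout is NHWC throughout, float32. Convolutions are 'same'-padded and
implemented by im2col (stride-tricks sliding windows + one matmul), which is
fast enough for the small working crops this package trains on. Each layer
caches what its backward pass needs; ``Sequential`` chains them.

This is intentionally a minimal engine: stride-1 convs, 2x2 max pooling,
dense layers, ReLU — exactly what the two model heads require.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2D(Layer):
    """Stride-1 'same' 2-D convolution (cross-correlation), He-initialised."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * cin))
        self.k = k
        self.W = Param(rng.normal(0.0, scale, (cin * k * k, cout)))
        self.b = Param(np.zeros(cout))
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.k // 2
        xpad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        # cols[n, y, x, c, i, j] = xpad[n, y+i, x+j, c]
        cols = sliding_window_view(xpad, (self.k, self.k), axis=(1, 2))
        cols = np.ascontiguousarray(cols).reshape(n * h * w, c * self.k * self.k)
        self._cols, self._xshape = cols, x.shape
        out = cols @ self.W.value + self.b.value
        return out.reshape(n, h, w, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        k, p = self.k, self.k // 2
        d2 = dout.reshape(n * h * w, -1)
        self.W.grad += self._cols.T @ d2
        self.b.grad += d2.sum(axis=0)
        dcols = (d2 @ self.W.value.T).reshape(n, h, w, c, k, k)
        dxpad = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxpad[:, i : i + h, j : j + w, :] += dcols[:, :, :, :, i, j]
        return dxpad[:, p : p + h, p : p + w, :] if p else dxpad

    def params(self) -> list[Param]:
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling; odd trailing rows/columns are edge-padded first."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._orig = (h, w)
        if h % 2 or w % 2:
            x = np.pad(x, ((0, 0), (0, h % 2), (0, w % 2), (0, 0)), mode="edge")
            h, w = x.shape[1:3]
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        # split gradient among ties so it stays well-defined
        self._mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
        self._padded = (h, w)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        c = dout.shape[-1]
        h, w = self._padded
        dx = (self._mask * dout[:, :, None, :, None, :]).reshape(n, h, w, c)
        oh, ow = self._orig
        return np.ascontiguousarray(dx[:, :oh, :ow, :])


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / cin)
        self.W = Param(rng.normal(0.0, scale, (cin, cout)))
        self.b = Param(np.zeros(cout))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def state_hash(layer: Layer) -> bytes:
    """Digest of all parameter values (for frozen-weights assertions)."""
    import hashlib

    h = hashlib.sha256()
    for p in layer.params():
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.digest()
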