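"""Minimal NumPy neural-network layers and the rmsprop optimizer.

Just enough machinery for the small reference CNN: 3x3 convolutions via
im2col, ReLU, 2x2 max pooling, dense layers, softmax cross-entropy, and
root-mean-square-propagation updates. Tensors are NHWC float32/float64.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: forward/backward plus named parameter access."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Conv2d(Layer):
    """3x3 same-padding convolution over NHWC input, He-initialized."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        self.k = kernel
        fan_in = kernel * kernel * in_channels
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_channels))
        self.b = np.zeros(out_channels)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        b, h, w, c = x.shape
        windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # windows: (B, H, W, C, k, k) -> (B*H*W, k*k*C)
        cols = windows.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * w, k * k * c)
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        self._shape = x.shape
        self._cols = self._im2col(x)
        out = self._cols @ self.w + self.b
        return out.reshape(b, h, w, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        k = self.k
        pad = k // 2
        g = grad.reshape(b * h * w, -1)
        self.dw = self._cols.T @ g
        self.db = g.sum(axis=0)
        dcols = (g @ self.w.T).reshape(b, h, w, k, k, c)
        dx = np.zeros((b, h + 2 * pad, w + 2 * pad, c))
        for i in range(k):
            for j in range(k):
                dx[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dx[:, pad : pad + h, pad : pad + w, :]

    def params(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {"w": self.dw, "b": self.db}


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2(Layer):
    """2x2, stride-2 max pooling; input H and W must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        blocks = x.reshape(b, h // 2, 2, w // 2, 2, c)
        out = blocks.max(axis=(2, 4))
        mask = blocks == out[:, :, None, :, None, :]
        # split gradient evenly across ties for exactness of the chain rule
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        g = grad[:, :, None, :, None, :] * self._mask
        return g.reshape(b, h, w, c)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.b = np.zeros(out_features)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {"w": self.dw, "b": self.db}


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(probs[np.arange(n), targets] + 1e-12)))
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n


class RMSProp:
    """Root-mean-square propagation: cache = rho*cache + (1-rho)*g^2."""

    def __init__(self, learning_rate: float = 1e-4, rho: float = 0.9, eps: float = 1e-7):
        self.lr = learning_rate
        self.rho = rho
        self.eps = eps
        self._cache: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers: list[Layer]) -> None:
        for li, layer in enumerate(layers):
            params, grads = layer.params(), layer.grads()
            if not params:
                continue
            cache = self._cache.setdefault(li, {k: np.zeros_like(v) for k, v in params.items()})
            for name, p in params.items():
                g = grads[name]
                cache[name] = self.rho * cache[name] + (1.0 - self.rho) * g * g
                p -= self.lr * g / (np.sqrt(cache[name]) + self.eps)
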