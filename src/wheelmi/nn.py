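"""Minimal seeded CNN engine (numpy): layers, backprop, Adam.

Sized for the small 2-D feature grids this pipeline classifies (a few
hundred training samples of ~8 x 14 inputs), favouring determinism and
clarity over throughput.  Data layout is channels-last: (N, H, W, C).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm",
    "MaxPool2D",
    "Dropout",
    "Flatten",
    "Dense",
    "Activation",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.sum(onehot * np.log(probs + eps), axis=1)))


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameters are (value, grad) array pairs."""

    trainable: bool = False

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def describe(self) -> str:
        return type(self).__name__


class Conv2D(Layer):
    """3x3 (configurable) convolution with 'same' zero padding, stride 1."""

    trainable = True

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        fan_in = kernel * kernel * c_in
        self.W = _glorot(rng, (kernel, kernel, c_in, c_out), fan_in, c_out)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train):
        k = self.kernel
        p = k // 2
        self._xpad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        N, H, W, _ = x.shape
        out = np.zeros((N, H, W, self.W.shape[-1]))
        for di in range(k):
            for dj in range(k):
                patch = self._xpad[:, di : di + H, dj : dj + W, :]
                out += patch @ self.W[di, dj]
        out += self.b
        self._shape = x.shape
        return out

    def backward(self, grad):
        k = self.kernel
        p = k // 2
        N, H, W, _ = self._shape
        dxpad = np.zeros_like(self._xpad)
        self.dW[...] = 0.0
        for di in range(k):
            for dj in range(k):
                patch = self._xpad[:, di : di + H, dj : dj + W, :]
                # (kh,kw) weight grad: contract over N,H,W
                self.dW[di, dj] = np.tensordot(patch, grad, axes=([0, 1, 2], [0, 1, 2]))
                dxpad[:, di : di + H, dj : dj + W, :] += grad @ self.W[di, dj].T
        self.db[...] = grad.sum(axis=(0, 1, 2))
        return dxpad[:, p : p + H, p : p + W, :]

    def describe(self):
        return f"Conv2D({self.W.shape[-1]} filters, {self.kernel}x{self.kernel})"


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    trainable = True

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        self.dgamma[...] = (grad * self._xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        m = self._m
        gxhat = grad * self.gamma
        return (
            gxhat - gxhat.mean(axis=axes) - self._xhat * (gxhat * self._xhat).mean(axis=axes)
        ) / self._std

    def describe(self):
        return "BatchNorm"


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x, train):
        N, H, W, C = x.shape
        H2, W2 = H // 2, W // 2
        if H2 < 1 or W2 < 1:
            raise ValueError(f"input {H}x{W} too small for 2x2 pooling")
        cropped = x[:, : H2 * 2, : W2 * 2, :]
        windows = cropped.reshape(N, H2, 2, W2, 2, C).transpose(0, 1, 3, 2, 4, 5)
        flat = windows.reshape(N, H2, W2, 4, C)
        self._arg = flat.argmax(axis=3)
        self._inshape = x.shape
        return flat.max(axis=3)

    def backward(self, grad):
        N, H, W, C = self._inshape
        H2, W2 = H // 2, W // 2
        dflat = np.zeros((N, H2, W2, 4, C))
        idx = np.indices((N, H2, W2, C))
        dflat[idx[0], idx[1], idx[2], self._arg, idx[3]] = grad
        dwin = dflat.reshape(N, H2, W2, 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros(self._inshape)
        dx[:, : H2 * 2, : W2 * 2, :] = dwin.reshape(N, H2 * 2, W2 * 2, C)
        return dx

    def describe(self):
        return "MaxPool2D(2x2)"


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def describe(self):
        return f"Dropout({self.rate})"


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def describe(self):
        return "Flatten"


class Dense(Layer):
    trainable = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def describe(self):
        return f"Dense({self.W.shape[1]})"


_SELU_ALPHA = 1.6732632423543772
_SELU_LAMBDA = 1.0507009873554805


class Activation(Layer):
    def __init__(self, kind: str):
        if kind not in ("tanh", "relu", "selu", "linear"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, train):
        self._x = x
        if self.kind == "tanh":
            self._y = np.tanh(x)
            return self._y
        if self.kind == "relu":
            return np.maximum(x, 0.0)
        if self.kind == "selu":
            return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * (np.exp(x) - 1.0))
        return x

    def backward(self, grad):
        if self.kind == "tanh":
            return grad * (1.0 - self._y**2)
        if self.kind == "relu":
            return grad * (self._x > 0)
        if self.kind == "selu":
            return grad * _SELU_LAMBDA * np.where(
                self._x > 0, 1.0, _SELU_ALPHA * np.exp(self._x)
            )
        return grad

    def describe(self):
        return f"Activation({self.kind})"


class Sequential:
    """Layer stack ending in logits; softmax/cross-entropy live outside."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def summary(self) -> list[str]:
        return [layer.describe() for layer in self.layers]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.params(), weights):
            p[...] = w


class Adam:
    """Adam optimizer (bias-corrected first/second moments)."""

    def __init__(
        self,
        params,
        learning_rate: float = 0.001,
        beta_1: float = 0.9,
        beta_2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = learning_rate
        self.b1 = beta_1
        self.b2 = beta_2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
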