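"""Minimal feed-forward neural-network core: dense/conv layers with manual
backpropagation and SGD with Nesterov momentum and L2 weight decay.

This is the training engine behind the classifier contract.  It is small on
purpose: the layers needed for a compact convolutional backbone and a dense
fusion head, vectorized over minibatches, on the CPU.  Arrays are float64;
image batches are shaped (N, C, H, W).
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


DTYPE = np.float32  # training precision; adequate for SGD and keeps the CPU path fast


class Dense(Layer):
    """Affine layer y = xW + b with He-scaled initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)).astype(DTYPE))
        self.b = Parameter(np.zeros(n_out, dtype=DTYPE))
        self._x: np.ndarray | None = None

    def params(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Conv2d(Layer):
    """Valid-mode 2-D convolution (kernel k×k, stride 1) via sliding windows.

    ``first=True`` marks the network's first parameterized layer: the
    gradient with respect to its input is never needed and is skipped."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 first: bool = False):
        self.kernel = kernel
        self.first = first
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.W = Parameter(rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)).astype(DTYPE))
        self.b = Parameter(np.zeros(c_out, dtype=DTYPE))

    def params(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        self._x = x
        # windows: (N, C, H-k+1, W-k+1, k, k)
        self._win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        out = np.einsum("nchwij,ocij->nohw", self._win, self.W.value, optimize=True)
        return out + self.b.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        k = self.kernel
        self.W.grad += np.einsum("nchwij,nohw->ocij", self._win, grad, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        if self.first:
            return None
        pad = k - 1
        gpad = np.pad(grad, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        gwin = np.lib.stride_tricks.sliding_window_view(gpad, (k, k), axis=(2, 3))
        w_flip = self.W.value[:, :, ::-1, ::-1]
        return np.einsum("nohwij,ocij->nchw", gwin, w_flip, optimize=True)


class AvgPool(Layer):
    """Non-overlapping k×k average pooling; requires divisible spatial dims."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"spatial dims {h}x{w} not divisible by pool size {k}")
        self._shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.k
        g = grad[:, :, :, None, :, None] / (k * k)
        return np.broadcast_to(
            g, grad.shape[:2] + (grad.shape[2], k, grad.shape[3], k)
        ).reshape(self._shape)


class MaxPool(Layer):
    """Non-overlapping k×k max pooling; trailing rows/cols that do not fill a
    window are dropped."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        hk, wk = h // k, w // k
        self._in_shape = x.shape
        xt = x[:, :, : hk * k, : wk * k].reshape(n, c, hk, k, wk, k)
        out = xt.max(axis=(3, 5))
        self._mask = xt == out[:, :, :, None, :, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.k
        n, c, h, w = self._in_shape
        hk, wk = h // k, w // k
        g = self._mask * grad[:, :, :, None, :, None]
        out = np.zeros(self._in_shape)
        out[:, :, : hk * k, : wk * k] = g.reshape(n, c, hk * k, wk * k)
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:  # a first=True layer ends the chain
                break
        return grad


class SGDNesterov:
    """SGD with Nesterov momentum and decoupled-from-nothing classic L2 decay.

    Update (per parameter p with gradient g):
        d = g + weight_decay · p
        v ← momentum · v + d
        step = d + momentum · v   (Nesterov)   |   step = v   (plain momentum)
        p ← p − lr · step

    ``max_grad_norm`` rescales the global data-gradient norm when it exceeds
    the bound — a numerical safeguard against the momentum runaway a loss
    spike can trigger in single-precision; with the generous default it is
    inactive on healthy steps.
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float,
        momentum: float = 0.95,
        weight_decay: float = 0.0,
        nesterov: bool = True,
        max_grad_norm: float = 10.0,
    ):
        if lr < 0 or not 0 <= momentum < 1 or weight_decay < 0:
            raise ValueError("invalid optimizer hyperparameters")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.nesterov = nesterov
        self.max_grad_norm = max_grad_norm
        self._velocity = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        if self.max_grad_norm is not None:
            total = np.sqrt(sum(float((p.grad.astype(np.float64) ** 2).sum())
                                for p in self.params))
            if total > self.max_grad_norm:
                scale = self.max_grad_norm / total
                for p in self.params:
                    p.grad *= scale
        for p, v in zip(self.params, self._velocity):
            d = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v += d
            step = d + self.momentum * v if self.nesterov else v
            p.value -= self.lr * step
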