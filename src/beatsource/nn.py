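"""Minimal numpy building blocks for the 1D-CNN: layers, loss, optimizer.

Internal tensor layout is channels-last, (batch, length, channels), which
lets the convolution run as one BLAS matmul over im2col patches.  All
parameters and activations are float32.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> Dict[str, np.ndarray]:
        return {}

    def grads(self) -> Dict[str, np.ndarray]:
        return {}


class Conv1d(Layer):
    """Valid (no-padding) 1-D convolution, stride 1, He-initialised."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        std = np.sqrt(2.0 / (in_channels * kernel_size))
        self.w = rng.normal(0.0, std, size=(in_channels * kernel_size, out_channels)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self._cols = None
        self.dw = None
        self.db = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, cin = x.shape
        l_out = length - self.k + 1
        if l_out < 1:
            raise ValueError("input shorter than kernel")
        # (n, l_out, cin, k) view -> (n, l_out, cin*k) contiguous patches
        cols = sliding_window_view(x, self.k, axis=1).reshape(n, l_out, cin * self.k)
        self._cols = cols
        return cols @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, l_out, _ = dy.shape
        cols2 = self._cols.reshape(-1, self.cin * self.k)
        dy2 = dy.reshape(-1, self.cout)
        self.dw = (cols2.T @ dy2).astype(np.float32)
        self.db = dy2.sum(axis=0)
        dcols = (dy @ self.w.T).reshape(n, l_out, self.cin, self.k)
        dx = np.zeros((n, l_out + self.k - 1, self.cin), dtype=np.float32)
        for j in range(self.k):
            dx[:, j:j + l_out, :] += dcols[:, :, :, j]
        self._cols = None
        return dx

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool1d(Layer):
    """Non-overlapping max pooling along the length axis; remainder dropped."""

    def __init__(self, pool: int):
        self.p = pool

    def forward(self, x):
        n, length, c = x.shape
        lp = length // self.p
        if lp < 1:
            raise ValueError("input shorter than pool size")
        self._in_shape = x.shape
        xt = x[:, : lp * self.p].reshape(n, lp, self.p, c)
        self._idx = xt.argmax(axis=2)
        return np.take_along_axis(xt, self._idx[:, :, None, :], axis=2).squeeze(2)

    def backward(self, dy):
        n, length, c = self._in_shape
        lp = length // self.p
        dxt = np.zeros((n, lp, self.p, c), dtype=np.float32)
        np.put_along_axis(dxt, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((n, length, c), dtype=np.float32)
        dx[:, : lp * self.p] = dxt.reshape(n, lp * self.p, c)
        self._idx = None
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / in_features)
        self.w = rng.normal(0.0, std, size=(in_features, out_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        dx = dy @ self.w.T
        self._x = None
        return dx

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class Sequential:
    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> List[tuple]:
        out = []
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                out.append((f"{i}.{name}", layer, name, arr))
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {key: arr.copy() for key, _, _, arr in self.parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for key, layer, name, arr in self.parameters():
            arr[...] = state[key]

    def n_parameters(self) -> int:
        return sum(arr.size for _, _, _, arr in self.parameters())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    eps = np.finfo(np.float32).tiny
    loss = float(-np.mean(np.log(p[np.arange(n), y] + eps)))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32), p


class Adam:
    """Adam with the standard defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, model: Sequential, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {key: np.zeros_like(arr) for key, _, _, arr in model.parameters()}
        self.v = {key: np.zeros_like(arr) for key, _, _, arr in model.parameters()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for key, layer, name, arr in self.model.parameters():
            g = layer.grads()[name]
            m = self.m[key]
            v = self.v[key]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            arr -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
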