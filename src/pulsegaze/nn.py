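"""Minimal numpy neural-network core: 1D convolution, dense layers,
ReLU, dropout, softmax cross-entropy, and Adam.

Forward and backward passes are written directly against the array
shapes (im2col for the convolutions); there is no autograd.  The layer
set is exactly what the two fatigue CNNs and the BiLSTM head need, and
training is deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "Dense",
    "ReLU",
    "Dropout",
    "Flatten",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and the gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + eps)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-padding, stride-1 1D convolution: (B, C, L) -> (B, F, L-k+1)."""

    def __init__(self, in_channels: int, filters: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel
        self.kernel = kernel
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(filters, in_channels, kernel)),
            "b": np.zeros(filters),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False, rng=None):
        self._x = x
        k = self.kernel
        # im2col: (B, C, L-k+1, k) -> (B, L', C*k)
        col = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
        B, C, Lp, _ = col.shape
        self._col = col.transpose(0, 2, 1, 3).reshape(B, Lp, C * k)
        W2 = self.params["W"].reshape(self.params["W"].shape[0], -1)  # (F, C*k)
        y = self._col @ W2.T + self.params["b"]  # (B, L', F)
        return y.transpose(0, 2, 1)  # (B, F, L')

    def backward(self, dy):
        # dy: (B, F, L')
        W = self.params["W"]
        F, C, k = W.shape
        dyt = dy.transpose(0, 2, 1)  # (B, L', F)
        B, Lp, _ = dyt.shape
        dW2 = np.einsum("blf,blck->fck", dyt, self._col.reshape(B, Lp, C, k), optimize=True)
        self.grads["W"][...] = dW2
        self.grads["b"][...] = dyt.sum(axis=(0, 1))
        dx = np.zeros_like(self._x)
        for j in range(k):
            # contribution of kernel offset j to input positions i+j
            dx[:, :, j : j + Lp] += np.einsum("blf,fc->bcl", dyt, W[:, :, j], optimize=True)
        return dx


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim)),
            "b": np.zeros(out_dim),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"][...] = self._x.T @ dy
        self.grads["b"][...] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode (deterministic inference)."""

    def __init__(self, rate: float = 0.5):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        assert rng is not None, "training dropout needs an rng"
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]


class Adam:
    """Adam optimizer over a list of (layer, param-name) handles."""

    def __init__(self, handles, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.handles = handles
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(l.params[n]) for l, n in handles]
        self.v = [np.zeros_like(l.params[n]) for l, n in handles]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (layer, name) in enumerate(self.handles):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
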