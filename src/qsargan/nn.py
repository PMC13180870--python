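"""Minimal NumPy feed-forward stack used by the conditional GAN.

Dense / BatchNorm1d / LeakyReLU layers with explicit forward and backward
passes, a label-embedding table, the Adam optimiser, and numerically stable
sigmoid + binary-cross-entropy helpers.  Everything is float64 and driven by
an explicit ``numpy.random.Generator``, so training is bit-reproducible on a
fixed platform without any framework-level seeding.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits.

    Uses log(1+exp(-|z|)) so large logits never overflow.
    """
    z, y = logits, targets
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style init; fine for LeakyReLU nets of this size
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # in-place so the optimiser's (value, grad) references stay live
        self.gW[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class LeakyReLU:
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)

    def params(self):
        return []


class BatchNorm1d:
    """Standard batch normalisation with running statistics for eval mode."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.ggamma = np.zeros(n)
        self.gbeta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._inv_sd = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean) * self._inv_sd
            return self.gamma * self._xhat + self.beta
        inv_sd = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * (x - self.running_mean) * inv_sd + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        m = grad.shape[0]
        self.ggamma[...] = (grad * self._xhat).sum(axis=0)
        self.gbeta[...] = grad.sum(axis=0)
        gxhat = grad * self.gamma
        return (
            self._inv_sd
            / m
            * (m * gxhat - gxhat.sum(axis=0) - self._xhat * (gxhat * self._xhat).sum(axis=0))
        )

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class Sigmoid:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._s = sigmoid(x)
        return self._s

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._s * (1.0 - self._s)

    def params(self):
        return []


class Embedding:
    """Learned per-class vector, concatenated with the network input."""

    def __init__(self, n_labels: int, dim: int, rng: np.random.Generator):
        self.table = rng.normal(0.0, 1.0, size=(n_labels, dim))
        self.gtable = np.zeros_like(self.table)

    def forward(self, idx: np.ndarray) -> np.ndarray:
        self._idx = idx
        return self.table[idx]

    def backward(self, grad: np.ndarray) -> None:
        self.gtable[...] = 0.0
        np.add.at(self.gtable, self._idx, grad)

    def params(self):
        return [(self.table, self.gtable)]


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self._params = params  # list of (value, grad) array pairs; updated in place
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(v) for v, _ in params]
        self.v = [np.zeros_like(v) for v, _ in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (value, _) in enumerate(self._params):
            grad = self._params[i][1]
            self.m[i] = b1 * self.m[i] + (1 - b1) * grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
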