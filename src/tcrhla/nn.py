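"""Minimal feed-forward neural-network core on numpy.

Layers store their parameters and the activations needed for the backward
pass; composition is by ``Sequential`` or manual wiring in the model classes.
Implemented here because the networks in this package are small (a CDR3
autoencoder, categorical gene embeddings, a character CNN over allele names
and one-hidden-layer MLPs) and all training happens on a single CPU.

Conventions
-----------
* dense inputs are ``(n, d)``; sequence inputs are channels-last ``(n, L, C)``
* every layer exposes ``forward(x, train)`` and ``backward(grad)``;
  ``backward`` must follow the matching ``forward``
* classification heads return **logits**; the sigmoid / softmax and their
  losses are fused in :func:`bce_with_logits` and
  :func:`softmax_cross_entropy` for numerical stability
"""

from __future__ import annotations

import copy
from typing import Optional, Sequence

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.w = Param(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self._x: Optional[np.ndarray] = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Embedding(Module):
    """Lookup table; forward takes integer indices of any shape."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, 1.0 / np.sqrt(dim), size=(n_tokens, dim)))
        self._idx: Optional[np.ndarray] = None

    def params(self):
        return [self.w]

    def forward(self, idx, train=False):
        self._idx = np.asarray(idx)
        return self.w.value[self._idx]

    def backward(self, grad):
        np.add.at(self.w.grad, self._idx.reshape(-1),
                  grad.reshape(-1, self.w.value.shape[1]))
        return None  # indices carry no gradient


class Conv1d(Module):
    """Valid 1-D convolution over channels-last sequences (n, L, C_in)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.w = Param(rng.normal(0.0, scale, size=(kernel, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel
        self._x: Optional[np.ndarray] = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        n, L, _ = x.shape
        L_out = L - self.kernel + 1
        out = np.tile(self.b.value, (n, L_out, 1))
        for k in range(self.kernel):
            out += x[:, k:k + L_out, :] @ self.w.value[k]
        return out

    def backward(self, grad):
        x = self._x
        n, L, c_in = x.shape
        L_out = grad.shape[1]
        gx = np.zeros_like(x)
        for k in range(self.kernel):
            self.w.grad[k] += np.einsum("nlc,nld->cd", x[:, k:k + L_out, :], grad)
            gx[:, k:k + L_out, :] += grad @ self.w.value[k].T
        self.b.grad += grad.sum(axis=(0, 1))
        return gx


class MaxPool1d(Module):
    """Non-overlapping max pooling over the length axis (truncates remainder)."""

    def __init__(self, pool: int):
        self.pool = pool
        self._argmax = None
        self._shape = None

    def forward(self, x, train=False):
        n, L, c = x.shape
        L_out = L // self.pool
        xr = x[:, : L_out * self.pool, :].reshape(n, L_out, self.pool, c)
        self._argmax = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, grad):
        n, L_out, c = grad.shape
        gx = np.zeros(self._shape)
        gr = gx[:, : L_out * self.pool, :].reshape(n, L_out, self.pool, c)
        ni, li, ci = np.ogrid[:n, :L_out, :c]
        gr[ni, li, self._argmax, ci] = grad
        return gx


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Dropout(Module):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Module):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


# ---------------------------------------------------------------------------
# losses (fused with their output nonlinearity)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of sigmoid(z) vs y; returns (loss, dL/dz)."""
    z = z.reshape(-1)
    y = y.reshape(-1).astype(float)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / len(z)
    return loss, grad


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-position CE over the last axis; targets are integer class indices.

    ``logits`` is (..., C); the loss is averaged over all leading positions.
    """
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=-1, keepdims=True)
    flat_p = probs.reshape(-1, probs.shape[-1])
    flat_t = targets.reshape(-1)
    n = flat_t.shape[0]
    loss = float(-np.mean(np.log(flat_p[np.arange(n), flat_t] + 1e-12)))
    grad = flat_p.copy()
    grad[np.arange(n), flat_t] -= 1.0
    return loss, (grad / n).reshape(logits.shape)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with decoupled-from-nothing L2 weight decay added to the gradient."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad + self.wd * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def get_state(params: Sequence[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: Sequence[Param], state: Sequence[np.ndarray]) -> None:
    for p, s in zip(params, state):
        p.value[...] = s


def clone_state(state):
    return copy.deepcopy(state)
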