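"""Minimal 1D neural-network layer library (numpy, explicit backprop).

Layers operate on float32 arrays of shape (N, C, L) and cache whatever the
backward pass needs.  Gradients accumulate into ``Param.grad``; the backward
methods return the gradient with respect to the layer input, so composite
modules chain them in reverse order.  Correctness is guarded by
finite-difference gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "frozen")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.frozen = False


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int
              ) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d:
    """Cross-correlation along the temporal axis, no bias (BN follows)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.w = Param(he_normal(rng, (cout, cin, k), cin * k))
        self._cache = None

    def params(self):
        return {"w": self.w}

    def buffers(self):
        return {}

    def out_length(self, length: int) -> int:
        return (length + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, length = x.shape
        if c != self.cin:
            raise InvalidArgumentError(f"expected {self.cin} channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad))) if self.pad else x
        lout = self.out_length(length)
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = windows[:, :, :: self.stride, :][:, :, :lout, :]
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            n * lout, self.cin * self.k)
        wr = self.w.value.reshape(self.cout, -1)
        y = cols @ wr.T
        self._cache = (cols, n, lout, xp.shape[2])
        return np.ascontiguousarray(y.reshape(n, lout, self.cout).transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, n, lout, lp = self._cache
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(n * lout, self.cout)
        self.w.grad += (dyr.T @ cols).reshape(self.w.value.shape)
        dcols = (dyr @ self.w.value.reshape(self.cout, -1)).reshape(
            n, lout, self.cin, self.k)
        dxp = np.zeros((n, self.cin, lp), dtype=DTYPE)
        for i in range(self.k):
            dxp[:, :, i: i + self.stride * (lout - 1) + 1: self.stride] += \
                dcols[:, :, :, i].transpose(0, 2, 1)
        return dxp[:, :, self.pad: lp - self.pad] if self.pad else dxp


class BatchNorm1d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def set_buffer(self, name: str, value: np.ndarray) -> None:
        setattr(self, name, np.array(value, dtype=DTYPE, order="C"))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std.astype(DTYPE), train)
        return (self.gamma.value[None, :, None] * xhat
                + self.beta.value[None, :, None]).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, train = self._cache
        self.dgamma_update(dy, xhat)
        dxhat = dy * self.gamma.value[None, :, None]
        if not train:  # running statistics are constants in evaluation mode
            return (dxhat * inv_std[None, :, None]).astype(DTYPE)
        mean_dxhat = dxhat.mean(axis=(0, 2), keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        dx = inv_std[None, :, None] * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        return dx.astype(DTYPE)

    def dgamma_update(self, dy, xhat):
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return {}

    def buffers(self):
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0).astype(DTYPE)


class MaxPool1d:
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def params(self):
        return {}

    def buffers(self):
        return {}

    def out_length(self, length: int) -> int:
        return (length + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)),
                    constant_values=-np.inf) if self.pad else x
        lout = self.out_length(length)
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        windows = windows[:, :, :: self.stride, :][:, :, :lout, :]
        idx = windows.argmax(axis=-1)
        self._cache = (idx, n, c, lout, xp.shape[2])
        return np.ascontiguousarray(windows.max(axis=-1), dtype=DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, n, c, lout, lp = self._cache
        dxp = np.zeros((n, c, lp), dtype=DTYPE)
        ni, ci, li = np.meshgrid(np.arange(n), np.arange(c), np.arange(lout),
                                 indexing="ij")
        np.add.at(dxp, (ni, ci, li * self.stride + idx), dy)
        return dxp[:, :, self.pad: lp - self.pad] if self.pad else dxp


class GlobalAvgPool:
    def __init__(self):
        self._length = None

    def params(self):
        return {}

    def buffers(self):
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (np.repeat(dy[:, :, None], self._length, axis=2)
                / self._length).astype(DTYPE)


class Linear:
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.din, self.dout = din, dout
        self.w = Param(he_normal(rng, (dout, din), din))
        self.b = Param(np.zeros(dout))
        self._cache = None

    def params(self):
        return {"w": self.w, "b": self.b}

    def buffers(self):
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._cache = x
        return (x @ self.w.value.T + self.b.value).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.w.grad += dy.T @ x
        self.b.grad += dy.sum(axis=0)
        return (dy @ self.w.value).astype(DTYPE)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
    dlogits = probs
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(DTYPE)


class Adam:
    """Adam with the usual defaults; frozen parameters are skipped entirely."""

    def __init__(self, params: dict[str, Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad[...] = 0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, p in self.params.items():
            if p.frozen:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad**2
            p.value -= lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
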