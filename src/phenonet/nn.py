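"""Minimal CNN building blocks with manual backpropagation.

Layers operate on channels-last float32 arrays ``(N, H, W, C)`` (or ``(N, F)``
for dense layers).  Each layer caches what its backward pass needs during
``forward`` and accumulates parameter gradients into ``Param.grad``; call
:func:`zero_grads` between minibatches.  Convolutions are stride-1 with
"same" zero padding, implemented via im2col + BLAS matmul, which is the
right trade-off for the small residual networks this package trains.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "GlobalAvgPool",
    "Dense",
    "Adam",
    "softmax",
    "zero_grads",
]


class Param:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def zero_grads(params) -> None:
    for p in params:
        p.grad[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Conv2D:
    """Stride-1 'same' convolution, He-normal initialised."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (kernel, kernel, c_in, c_out))
        self.W = Param(w.astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        self._cols = None
        self._shape = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        # computed as a sum of k*k shifted (N*H*W, C) @ (C, F) products,
        # which beats a materialised im2col gather for these small nets
        k, p = self.kernel, self.kernel // 2
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        wf = self.W.value
        out = np.empty((n * h * w, self.c_out), dtype=np.float32)
        out[:] = self.b.value
        shifts = []
        for i in range(k):
            for j in range(k):
                xs = xp[:, i : i + h, j : j + w, :].reshape(-1, c)
                out += xs @ wf[i, j]
                shifts.append(xs)
        self._cols = shifts
        self._shape = (n, h, w, c)
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, p = self.kernel, self.kernel // 2
        n, h, w, c = self._shape
        d2 = dout.reshape(-1, self.c_out)
        self.b.grad += d2.sum(axis=0)
        wf = self.W.value
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        idx = 0
        for i in range(k):
            for j in range(k):
                self.W.grad[i, j] += self._cols[idx].T @ d2
                dxp[:, i : i + h, j : j + w, :] += (d2 @ wf[i, j].T).reshape(
                    n, h, w, c
                )
                idx += 1
        return dxp[:, p : p + h, p : p + w, :]


class BatchNorm:
    """Batch normalisation over all non-channel axes.

    Works for both 4-d conv maps and 2-d dense activations.  Running
    statistics (momentum 0.9) are used when ``train=False``.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, axes, x.size // x.shape[-1])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, m = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        # standard batch-norm backward over the normalisation axes
        return inv_std * (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).mean(axis=axes)
        )


class ReLU:
    def __init__(self):
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(np.float32, copy=False)


class GlobalAvgPool:
    """(N, H, W, C) -> (N, C) spatial mean."""

    def __init__(self):
        self._hw = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._hw = x.shape[1:3]
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._hw
        return np.broadcast_to(
            dout[:, None, None, :] / (h * w), (dout.shape[0], h, w, dout.shape[1])
        ).astype(np.float32)


class GlobalAvgMaxPool:
    """(N, H, W, C) -> (N, 2C): concatenated spatial mean and spatial max.

    The mean half carries extensive signal (how much of the frame is
    active); the max half preserves peak activations of spatially small
    structures that a plain average would dilute.
    """

    def __init__(self):
        self._hw = None
        self._argmax = None
        self._c = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        self._hw = (h, w)
        self._c = c
        flat = x.reshape(n, h * w, c)
        self._argmax = flat.argmax(axis=1)  # (N, C)
        return np.concatenate([flat.mean(axis=1), flat.max(axis=1)], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._hw
        n, c = dout.shape[0], self._c
        davg, dmax = dout[:, :c], dout[:, c:]
        dx = np.broadcast_to(
            davg[:, None, :] / (h * w), (n, h * w, c)
        ).astype(np.float32).copy()
        ni = np.repeat(np.arange(n), c)
        ci = np.tile(np.arange(c), n)
        dx[ni, self._argmax.ravel(), ci] += dmax.ravel()
        return dx.reshape(n, h, w, c)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.W = Param(w.astype(np.float32))
        self.b = Param(np.zeros(n_out, dtype=np.float32))
        self._x = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Adam:
    """Adam optimiser over a list of :class:`Param`."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
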