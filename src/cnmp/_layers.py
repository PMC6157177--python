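"""Minimal NumPy neural-network layers with hand-written backprop.

Only what the coding network and the MLP fusion head need: valid convolution
(stride 1, no padding) via im2col + GEMM, overlapping max-pooling, batch
normalization, ReLU, a dense layer, and softmax cross-entropy.  Layout is
channels-last ``(batch, height, width, channels)`` throughout.

Convolution batches are processed in chunks so the im2col buffer never
exceeds ``_MAX_COL_FLOATS`` floats; the buffer is recomputed in the backward
pass instead of cached.  All parameters are float32.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def params(self) -> list[dict]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv(Layer):
    """Valid cross-correlation, stride 1, He-initialized, computed via FFT.

    Forward, input gradient and weight gradient are all correlations /
    convolutions, so each is one elementwise product in the 2-D Fourier
    domain with a channel contraction — far cheaper than im2col for the
    large (8-11 px) kernels this architecture uses.  Weights are stored as
    ``(k, k, c_in, c_out)`` float32.

    ``first_layer=True`` skips the input gradient in backward (the image
    itself needs no gradient), removing the most expensive transposed
    convolution of the stack.
    """

    first_layer: bool = False

    def __init__(self, k: int, c_in: int, c_out: int, rng: np.random.Generator):
        self.k, self.c_in, self.c_out = k, c_in, c_out
        fan_in = k * k * c_in
        self.W = (rng.standard_normal((k, k, c_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self) -> list[dict]:
        return [
            {"value": self.W, "grad": self.dW, "vel": self.vW},
            {"value": self.b, "grad": self.db, "vel": self.vb},
        ]

    def _fft_x(self, x: np.ndarray) -> np.ndarray:
        # (B, H, Wf, C) spectrum of the input, transform over the spatial axes
        return sfft.rfft2(x, axes=(1, 2))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, _ = x.shape
        oh, ow = h - self.k + 1, w - self.k + 1
        if oh < 1 or ow < 1:
            raise ValueError(f"conv kernel {self.k} larger than input {h}x{w}")
        X = self._fft_x(x)
        K = sfft.rfft2(self.W, s=(h, w), axes=(0, 1))  # (H, Wf, C, F)
        # correlation = ifft(X . conj(K)); the first oh x ow block is the valid part
        Y = np.einsum("bhwc,hwcf->bhwf", X, np.conj(K), optimize=True)
        y = sfft.irfft2(Y, s=(h, w), axes=(1, 2))[:, :oh, :ow, :]
        self._x = x if train else None
        return np.ascontiguousarray(y, dtype=np.float32) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None, "backward before forward(train=True)"
        h, w = x.shape[1], x.shape[2]
        k = self.k
        self.db[...] = dy.sum(axis=(0, 1, 2))
        X = self._fft_x(x)
        DY = sfft.rfft2(dy, s=(h, w), axes=(1, 2))  # zero-padded to input size
        # dW = valid correlation of x with dy, summed over the batch
        Gw = np.einsum("bhwc,bhwf->hwcf", X, np.conj(DY), optimize=True)
        self.dW[...] = sfft.irfft2(Gw, s=(h, w), axes=(0, 1))[:k, :k, :, :]
        self._x = None
        if self.first_layer:
            return np.zeros_like(x)
        # dx = full convolution of dy with W (channels contracted on c_out)
        K = sfft.rfft2(self.W, s=(h, w), axes=(0, 1))
        Gx = np.einsum("bhwf,hwcf->bhwc", DY, K, optimize=True)
        return np.ascontiguousarray(sfft.irfft2(Gx, s=(h, w), axes=(1, 2)), dtype=np.float32)


class MaxPool(Layer):
    """Max pooling with window k and stride s (overlapping when k > s)."""

    def __init__(self, k: int = 5, s: int = 2):
        self.k, self.s = k, s
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, s = self.k, self.s
        h, w = x.shape[1], x.shape[2]
        if h < k or w < k:
            raise ValueError(f"pool window {k} larger than input {h}x{w}")
        oh = (h - k) // s + 1
        ow = (w - k) // s + 1
        # running max over the k*k window offsets keeps memory traffic low
        y = np.full((x.shape[0], oh, ow, x.shape[3]), -np.inf, dtype=x.dtype)
        arg = np.zeros(y.shape, dtype=np.int16) if train else None
        for r in range(k):
            for c in range(k):
                cand = x[:, r : r + (oh - 1) * s + 1 : s, c : c + (ow - 1) * s + 1 : s, :]
                better = cand > y
                np.copyto(y, cand, where=better)
                if train:
                    arg[better] = r * k + c
        self._cache = (x.shape, arg) if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        x_shape, arg = self._cache
        k, s = self.k, self.s
        b, oh, ow, c = dy.shape
        bi, ohi, owi, ci = np.indices((b, oh, ow, c), sparse=False)
        r = ohi * s + arg // k
        col = owi * s + arg % k
        dx = np.zeros(x_shape, dtype=dy.dtype)
        np.add.at(dx, (bi, r, col, ci), dy)
        self._cache = None
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, height, width)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.vgamma = np.zeros_like(self.gamma)
        self.vbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def params(self) -> list[dict]:
        return [
            {"value": self.gamma, "grad": self.dgamma, "vel": self.vgamma},
            {"value": self.beta, "grad": self.dbeta, "vel": self.vbeta},
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 1, 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv, x.shape[0] * x.shape[1] * x.shape[2])
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv, n = self._cache
        axes = (0, 1, 2)
        self.dgamma[...] = (dy * xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) * inv
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        self._mask = x > 0 if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        dx = dy * self._mask
        self._mask = None
        return dx


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._shape is not None
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self) -> list[dict]:
        return [
            {"value": self.W, "grad": self.dW, "vel": self.vW},
            {"value": self.b, "grad": self.db, "vel": self.vb},
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity when rate == 0 or at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y_idx: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits for 0-based labels."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(np.clip(p[np.arange(n), y_idx], 1e-12, None))))
    grad = p.copy()
    grad[np.arange(n), y_idx] -= 1.0
    return loss, (grad / n).astype(np.float32)


def sgd_momentum_step(layers: list[Layer], lr: float, momentum: float = 0.9) -> None:
    for layer in layers:
        for p in layer.params():
            p["vel"] *= momentum
            p["vel"] -= lr * p["grad"]
            p["value"] += p["vel"]
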