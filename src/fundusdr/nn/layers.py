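"""Neural-network layers with explicit forward/backward passes.

All layers operate on ``(N, H, W, C)`` (or ``(N, F)`` for dense) float
arrays.  Each layer caches what its backward pass needs during
``forward(..., train=True)``; parameters and their gradients live on the
layer as ``params`` / ``grads`` dicts so the optimizer can address them
uniformly.  Correctness of every backward pass is pinned by numerical
gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from ..errors import InvalidInputError


class Layer:
    """Base class: stateless identity."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) zero-padded 'same' -> (N*H*W, C*k*k) patch matrix."""
    p_lo = (k - 1) // 2
    p_hi = k - 1 - p_lo
    xp = np.pad(x, ((0, 0), (p_lo, p_hi), (p_lo, p_hi), (0, 0)))
    # windows: (N, H, W, C, k, k) viewing the padded array
    win = sliding_window_view(xp, (k, k), axis=(1, 2))
    n, h, w = x.shape[0], x.shape[1], x.shape[2]
    return win.reshape(n * h * w, -1)


class Conv2D(Layer):
    """3x3 (configurable) same-padding convolution, stride 1.

    Weights are stored as an ``(out_ch, in_ch*k*k)`` matrix; the forward pass
    is an im2col matrix product.  The input gradient is computed as a
    correlation with the spatially flipped, channel-transposed kernel, which
    keeps the backward pass itself a single im2col product.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 needs_input_grad: bool = True) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.needs_input_grad = needs_input_grad
        self.params = {
            "W": np.zeros((out_ch, in_ch * kernel * kernel)),
            "b": np.zeros(out_ch),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols = _im2col(x, self.k)
        out = cols @ self.params["W"].T + self.params["b"]
        if train:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(x.shape[0], x.shape[1], x.shape[2], self.out_ch)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, _ = dout.shape
        dflat = dout.reshape(n * h * w, self.out_ch)
        self.grads["W"][...] = dflat.T @ self._cols
        self.grads["b"][...] = dflat.sum(axis=0)
        if not self.needs_input_grad:  # first layer: nothing consumes dx
            return np.zeros(self._xshape, dtype=dout.dtype)
        # dx = correlation of dout with W flipped in space, swapped in channels
        wk = self.params["W"].reshape(self.out_ch, self.in_ch, self.k, self.k)
        wk_flip = wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (in, out, k, k)
        cols_d = _im2col(dout, self.k)
        dx = cols_d @ wk_flip.reshape(self.in_ch, -1).T
        return dx.reshape(self._xshape)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2, floor division on odd sides (no padding)."""

    def __init__(self, kernel: int = 2) -> None:
        super().__init__()
        self.k = kernel

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.k
        n, h, w, c = x.shape
        h2, w2 = h // k, w // k
        xc = x[:, : h2 * k, : w2 * k, :]
        win = xc.reshape(n, h2, k, w2, k, c).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(n, h2, w2, c, k * k)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._xshape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        n, h, w, c = self._xshape
        h2, w2 = h // k, w // k
        dwin = np.zeros((n, h2, w2, c, k * k), dtype=dout.dtype)
        np.put_along_axis(dwin, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        dx[:, : h2 * k, : w2 * k, :] = (
            dwin.reshape(n, h2, w2, c, k, k)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h2 * k, w2 * k, c)
        )
        return dx


class LocalResponseNorm(Layer):
    """Across-channel local response normalization (AlexNet/Caffe style).

    ``y_i = x_i / (k + alpha/n * sum_{j in N(i)} x_j^2)^beta`` with the sum
    over a window of ``n`` adjacent channels centred on ``i``.
    """

    def __init__(self, n: int = 5, alpha: float = 1e-4, beta: float = 0.75,
                 k: float = 1.0) -> None:
        super().__init__()
        self.n, self.alpha, self.beta, self.kk = n, alpha, beta, k
        self._ones = np.ones(n)

    def _window_sum(self, t: np.ndarray) -> np.ndarray:
        return ndimage.correlate1d(t, self._ones, axis=-1, mode="constant", cval=0.0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        scale = self.kk + (self.alpha / self.n) * self._window_sum(x * x)
        out = x * scale ** (-self.beta)
        if train:
            self._x, self._scale, self._out = x, scale, out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        t = dout * self._out / self._scale
        return (
            dout * self._scale ** (-self.beta)
            - (2.0 * self.alpha * self.beta / self.n) * self._x * self._window_sum(t)
        )


class BatchNorm(Layer):
    """Per-channel batch normalization (configurable alternative to LRN)."""

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.9) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(n_ch), "beta": np.zeros(n_ch)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        # exponential averages stored in zero-debiased form: the raw sums are
        # divided by (1 - momentum^t) so early inference is not dragged
        # toward the 0/1 initialization
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self._raw_mean = np.zeros(n_ch)
        self._raw_var = np.zeros(n_ch)
        self._t = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self._t += 1
            self._raw_mean = m * self._raw_mean + (1 - m) * mean
            self._raw_var = m * self._raw_var + (1 - m) * var
            debias = 1.0 - m ** self._t
            self.running_mean = self._raw_mean / debias
            self.running_var = self._raw_var / debias
            self._xhat = (x - mean) / np.sqrt(var + self.eps)
            self._istd = 1.0 / np.sqrt(var + self.eps)
            self._m = np.prod([x.shape[a] for a in axes])
            return self.params["gamma"] * self._xhat + self.params["beta"]
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = tuple(range(dout.ndim - 1))
        self.grads["gamma"][...] = (dout * self._xhat).sum(axis=axes)
        self.grads["beta"][...] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        m = self._m
        return (self._istd / m) * (
            m * dxhat
            - dxhat.sum(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int) -> None:
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.params = {"W": np.zeros((n_in, n_out)), "b": np.zeros(n_out)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.n_in:
            raise InvalidInputError(
                f"dense layer expects {self.n_in} features, got {x.shape[1]}"
            )
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise InvalidInputError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
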