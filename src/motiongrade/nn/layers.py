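"""Minimal 3D neural-network layers in NumPy.

The grader network is small (~1e5 parameters), so convolutions are run as
im2col + BLAS matmuls in float32. Feature maps are laid out channels-last,
(batch, depth, height, width, channels): the im2col gather then copies
contiguous channel runs and the conv output needs no transpose, which is
what makes CPU training practical. Each layer exposes
``forward(x, train)`` and ``backward(dy)``; parameter gradients accumulate
in ``grads`` between ``zero_grad()`` calls.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = [
    "Layer",
    "Conv3D",
    "MaxPool3D",
    "GlobalAvgPool3D",
    "Flatten",
    "Dense",
    "ReLU",
    "Dropout",
    "Sigmoid",
]


class Layer:
    name: str = "layer"

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        """Shape transform on a single sample, channels-last (D, H, W, C)."""
        raise NotImplementedError


def _im2col(x: np.ndarray, k: tuple[int, int, int]) -> np.ndarray:
    """(D, H, W, C) -> (D'*H'*W', kd*kh*kw*C) patch matrix, valid positions."""
    win = sliding_window_view(x, k, axis=(0, 1, 2))  # (D',H',W',C,kd,kh,kw)
    dp, hp, wp, c = win.shape[:4]
    cols = win.transpose(0, 1, 2, 4, 5, 6, 3).reshape(
        dp * hp * wp, k[0] * k[1] * k[2] * c
    )
    return np.ascontiguousarray(cols)


class Conv3D(Layer):
    """Valid (unpadded) 3D convolution, stride 1, with bias.

    Weights are stored as (kd, kh, kw, cin, cout) so the flattened matrix
    matches the im2col patch ordering directly.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: tuple[int, int, int],
        rng: np.random.Generator | None = None,
        name: str = "conv",
        skip_input_grad: bool = False,
    ):
        self.cin, self.cout, self.k = in_channels, out_channels, tuple(kernel_size)
        self.name = name
        self.skip_input_grad = skip_input_grad  # first layer: dx is never used
        fan_in = in_channels * int(np.prod(self.k))
        rng = rng or np.random.default_rng(0)
        self.W = (rng.standard_normal((*self.k, in_channels, out_channels)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._cols: list[np.ndarray] | None = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return {"W": self.dW, "b": self.db}

    def out_shape(self, in_shape):
        d, h, w, c = in_shape
        od, oh, ow = d - self.k[0] + 1, h - self.k[1] + 1, w - self.k[2] + 1
        if min(od, oh, ow) < 1:
            raise ValueError(
                f"{self.name}: spatial dims underflow ({od},{oh},{ow}) "
                f"from input {in_shape} with kernel {self.k}"
            )
        return (od, oh, ow, self.cout)

    def forward(self, x, train=False):
        self._x = x if train else None
        b = x.shape[0]
        od, oh, ow, _ = self.out_shape(x.shape[1:])
        wmat = self.W.reshape(-1, self.cout)
        out = np.empty((b, od, oh, ow, self.cout), dtype=np.float32)
        self._cols = [] if train else None
        for i in range(b):
            cols = _im2col(x[i], self.k)
            if train:
                self._cols.append(cols)
            out[i] = (cols @ wmat + self.b).reshape(od, oh, ow, self.cout)
        return out

    def backward(self, dy):
        x = self._x
        assert x is not None, "backward() requires forward(train=True)"
        b = x.shape[0]
        kd, kh, kw = self.k
        self.db += dy.sum(axis=(0, 1, 2, 3))
        dwmat = self.dW.reshape(-1, self.cout)
        if not self.skip_input_grad:
            # data gradient = full conv of dy with the flipped kernel
            wflip = self.W[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)
            wflip_mat = np.ascontiguousarray(wflip.reshape(-1, self.cin))
            pad = ((kd - 1, kd - 1), (kh - 1, kh - 1), (kw - 1, kw - 1), (0, 0))
        dx = np.zeros_like(x) if not self.skip_input_grad else np.empty(0)
        for i in range(b):
            dyi = dy[i].reshape(-1, self.cout)
            dwmat += self._cols[i].T @ dyi
            if not self.skip_input_grad:
                dcols = _im2col(np.pad(dy[i], pad), self.k)
                dx[i] = (dcols @ wflip_mat).reshape(x.shape[1:])
        self._cols = None  # free the cached patch matrices promptly
        return dx


class MaxPool3D(Layer):
    """2x2x2 max pooling, stride 2; odd trailing voxels are dropped."""

    def __init__(self, name: str = "pool"):
        self.name = name
        self._x: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def out_shape(self, in_shape):
        d, h, w, c = in_shape
        if min(d, h, w) < 2:
            raise ValueError(f"{self.name}: input {in_shape} too small to pool")
        return (d // 2, h // 2, w // 2, c)

    @staticmethod
    def _windows(x):
        b, d, h, w, c = x.shape
        xc = x[:, : d // 2 * 2, : h // 2 * 2, : w // 2 * 2]
        return xc.reshape(b, d // 2, 2, h // 2, 2, w // 2, 2, c)

    def forward(self, x, train=False):
        win = self._windows(x)
        y = win.max(axis=(2, 4, 6))
        if train:
            self._x, self._y = x, y
        return y

    def backward(self, dy):
        x, y = self._x, self._y
        assert x is not None and y is not None
        win = self._windows(x)
        yb = y[:, :, None, :, None, :, None, :]
        mask = win == yb
        counts = mask.sum(axis=(2, 4, 6), keepdims=True)
        g = mask * (dy[:, :, None, :, None, :, None, :] / counts)
        dx = np.zeros_like(x)
        b, d, h, w, c = x.shape
        dx[:, : d // 2 * 2, : h // 2 * 2, : w // 2 * 2] = g.reshape(
            b, d // 2 * 2, h // 2 * 2, w // 2 * 2, c
        )
        return dx


class GlobalAvgPool3D(Layer):
    """Average each channel over all spatial positions -> (B, C)."""

    def __init__(self, name: str = "gap"):
        self.name = name
        self._shape: tuple[int, ...] | None = None

    def out_shape(self, in_shape):
        return (in_shape[-1],)

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dy):
        b, d, h, w, c = self._shape
        return np.broadcast_to(
            dy[:, None, None, None, :] / (d * h * w), self._shape
        ).astype(np.float32).copy()


class Flatten(Layer):
    """Literal flattening of the feature volume (alternative to GAP)."""

    def __init__(self, name: str = "flatten"):
        self.name = name
        self._shape: tuple[int, ...] | None = None

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None, name: str = "dense"):
        self.n_in, self.n_out = n_in, n_out
        self.name = name
        rng = rng or np.random.default_rng(0)
        self.W = (rng.standard_normal((n_in, n_out)) *
                  np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return {"W": self.dW, "b": self.db}

    def out_shape(self, in_shape):
        if in_shape != (self.n_in,):
            raise ValueError(f"{self.name}: expected ({self.n_in},), got {in_shape}")
        return (self.n_out,)

    def forward(self, x, train=False):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, dy):
        assert self._x is not None
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._mask = None

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None,
                 name: str = "dropout"):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self.name = name
        self._mask = None

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Sigmoid(Layer):
    def __init__(self, name: str = "sigmoid"):
        self.name = name
        self._y = None

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False):
        y = expit(x)
        if train:
            self._y = y
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)
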