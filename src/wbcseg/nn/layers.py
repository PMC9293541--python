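"""Layer primitives (NCHW layout) with explicit forward/backward passes."""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "UpsampleNearest2x",
    "Dropout",
    "Linear",
]


class Layer:
    """Base class: parameters live in ``params``, gradients in ``grads``.

    Arrays in ``params``/``grads``/``buffers`` are updated in place so an
    optimizer can hold direct references.
    """

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}  # nontrainable state

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_trainable(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def n_nontrainable(self) -> int:
        return int(sum(b.size for b in self.buffers.values()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = dict(self.params)
        out.update(self.buffers)
        return out


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patches for a stride-1 same convolution."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # sliding_window_view: (N, C, H, W, k, k)
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(col)


def _col2im(dcol: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    n, c, h, w = x_shape
    dpad = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    dcol = dcol.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dpad[:, :, i : i + h, j : j + w] += dcol[:, :, :, :, i, j]
    if pad:
        return dpad[:, :, pad:-pad, pad:-pad]
    return dpad


class Conv2d(Layer):
    """Stride-1 same-padding convolution; He-normal initialization."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        bias: bool = True,
    ) -> None:
        super().__init__()
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size * kernel_size
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in)
        )
        self.grads["W"] = np.zeros_like(self.params["W"])
        if bias:
            self.params["b"] = np.zeros(out_channels)
            self.grads["b"] = np.zeros(out_channels)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        col = _im2col(x, self.k, self.pad)
        out = col @ self.params["W"].T
        if "b" in self.params:
            out += self.params["b"]
        self._cache = (col, x.shape)
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        col, x_shape = self._cache
        n, _, h, w = x_shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.grads["W"][...] = dflat.T @ col
        if "b" in self.params:
            self.grads["b"][...] = dflat.sum(axis=0)
        dcol = dflat @ self.params["W"]
        return _col2im(dcol, x_shape, self.k, self.pad)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.grads["gamma"] = np.zeros(channels)
        self.grads["beta"] = np.zeros(channels)
        self.buffers["running_mean"] = np.zeros(channels)
        self.buffers["running_var"] = np.ones(channels)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["running_mean"] *= 1 - m
            self.buffers["running_mean"] += m * mean
            self.buffers["running_var"] *= 1 - m
            self.buffers["running_var"] += m * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][
            None, :, None, None
        ]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.grads["gamma"][...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][...] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        # batch-statistics backward (training-mode normalization)
        mean_dxhat = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) * inv_std[
            None, :, None, None
        ]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 requires even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        am = xr == out[:, :, :, None, :, None]
        # break ties toward the first occurrence to keep the adjoint exact
        flat = am.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self._argmask = (
            (flat & first)
            .reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
        )
        self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = self._argmask * dout[:, :, :, None, :, None]
        return dx.reshape(self._in_shape)


class UpsampleNearest2x(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.params["b"] = np.zeros(n_out)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = dout.T @ self._x
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"]
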