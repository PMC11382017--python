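"""Minimal seeded numpy layers with forward/backward passes.

Only what the trait-regression CNN needs: same-padding 3x3-style convolutions
(im2col), 2x2 max pooling, batch norm (2d affine, 1d optionally non-affine),
ReLU, dropout, flatten and linear layers.  All state is plain numpy so
checkpoints are deep-copyable and training is bitwise reproducible on a
single thread.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import ShapeError


class Layer:
    """Base layer: parameters in ``params``/``grads`` dicts keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k] = v.copy()


# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) column matrix, stride 1, same padding."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (N, C, H, W, k, k)
    return windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2d(Layer):
    """Stride-1 same-padding convolution via im2col."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.pad = kernel // 2
        fan_in = in_channels * kernel * kernel
        self.params["W"] = (
            rng.standard_normal((out_channels, fan_in)) * np.sqrt(2.0 / fan_in)
        ).astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ShapeError(
                f"Conv2d expects (N, {self.in_channels}, H, W), got {x.shape}"
            )
        self._x_shape = x.shape
        self._cols = _im2col(x, self.kernel, self.pad)
        n, _, h, w = x.shape
        out = np.einsum(
            "fk,nkp->nfp", self.params["W"], self._cols, optimize=True
        ) + self.params["b"][None, :, None]
        return out.reshape(n, self.out_channels, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h, w = dout.shape
        dflat = dout.reshape(n, f, h * w)
        self.grads["W"] = np.einsum("nfp,nkp->fk", dflat, self._cols, optimize=True)
        self.grads["b"] = dflat.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfp->nkp", self.params["W"], dflat, optimize=True)
        return _col2im(dcols, self._x_shape, self.kernel, self.pad)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2 (input spatial dims must be even)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ShapeError(f"MaxPool2d needs even spatial dims, got {h}x{w}")
        windows = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = windows.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        return (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng) -> None:
        super().__init__()
        self.in_features = in_features
        self.params["W"] = (
            rng.standard_normal((in_features, out_features))
            * np.sqrt(2.0 / in_features)
        ).astype(np.float32)
        self.params["b"] = np.zeros(out_features, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise ShapeError(
                f"Linear expects {self.in_features} inputs, got {x.shape[1]}"
            )
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class _BatchNorm(Layer):
    """Shared batch-norm core over a reduction axis set."""

    def __init__(self, num_features: int, affine: bool, momentum: float = 0.1) -> None:
        super().__init__()
        self.num_features = num_features
        self.affine = affine
        self.momentum = momentum
        self.eps = 1e-5
        if affine:
            self.params["gamma"] = np.ones(num_features, dtype=np.float32)
            self.params["beta"] = np.zeros(num_features, dtype=np.float32)
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)

    def _axes(self, x: np.ndarray) -> tuple:
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _shape(self, x: np.ndarray) -> tuple:
        return (1, -1) if x.ndim == 2 else (1, -1, 1, 1)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes, shp = self._axes(x), self._shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).reshape(shp).astype(x.dtype)
        self._xhat = (x - mean.reshape(shp).astype(x.dtype)) * self._inv_std
        out = self._xhat
        if self.affine:
            out = out * self.params["gamma"].reshape(shp) + self.params["beta"].reshape(shp)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes, shp = self._axes(dout), self._shape(dout)
        m = dout.size / self.num_features
        if self.affine:
            self.grads["gamma"] = (dout * self._xhat).sum(axis=axes)
            self.grads["beta"] = dout.sum(axis=axes)
            dxhat = dout * self.params["gamma"].reshape(shp)
        else:
            dxhat = dout
        # standard batch-norm gradient
        t1 = dxhat - dxhat.mean(axis=axes, keepdims=True)
        t2 = self._xhat * (dxhat * self._xhat).sum(axis=axes, keepdims=True) / m
        return self._inv_std * (t1 - t2)

    def state_dict(self) -> dict:
        state = super().state_dict()
        state["running_mean"] = self.running_mean.copy()
        state["running_var"] = self.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()
        super().load_state_dict(
            {k: v for k, v in state.items() if k not in ("running_mean", "running_var")}
        )


class BatchNorm2d(_BatchNorm):
    def __init__(self, num_features: int, momentum: float = 0.1) -> None:
        super().__init__(num_features, affine=True, momentum=momentum)


class BatchNorm1d(_BatchNorm):
    def __init__(self, num_features: int, affine: bool = True, momentum: float = 0.1) -> None:
        super().__init__(num_features, affine=affine, momentum=momentum)


class Dropout(Layer):
    """Inverted dropout with its own seeded generator (identity at eval)."""

    def __init__(self, rate: float, seed: int) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Sequential:
    """Ordered layer container with chained forward/backward."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def state_dict(self) -> list[dict]:
        return [layer.state_dict() for layer in self.layers]

    def load_state_dict(self, state: list[dict]) -> None:
        for layer, s in zip(self.layers, state):
            layer.load_state_dict(s)

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield (i, name), layer
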