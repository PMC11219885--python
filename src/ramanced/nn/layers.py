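"""Minimal 1-D neural-network layers with explicit backpropagation.

All layers operate on float64 arrays shaped (batch, channels, length) for
convolutional stages and (batch, features) for dense stages. Each layer
caches what its backward pass needs during ``forward(..., training=True)``
and accumulates parameter gradients in ``self.grads``. Every layer is
gradient-checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError

__all__ = [
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "BatchNormFlat",
    "Dense",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Flatten",
    "Dropout",
    "soft_threshold",
    "ShrinkageGate",
]


def soft_threshold(x, tau):
    """Soft-thresholding shrinkage: sign(x) * max(|x| - tau, 0), tau >= 0."""
    x = np.asarray(x, dtype=float)
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ConfigurationError("soft_threshold requires tau >= 0")
    return np.sign(x) * np.maximum(np.abs(x) - tau_arr, 0.0)


class Layer:
    """Base class: parameter dicts plus forward/backward hooks."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.sublayers: list["Layer"] = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def walk(self):
        """Yield this layer and all sublayers, depth-first."""
        yield self
        for sub in self.sublayers:
            yield from sub.walk()

    def n_parameters(self) -> int:
        return sum(p.size for lyr in self.walk() for p in lyr.params.values())


def _same_padding(length: int, kernel: int, stride: int) -> tuple[int, int]:
    out = -(-length // stride)  # ceil
    total = max((out - 1) * stride + kernel - length, 0)
    return total // 2, total - total // 2


class Conv1d(Layer):
    """1-D convolution (cross-correlation) with 'same' or no padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: str = "same",
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        scale = np.sqrt(2.0 / (in_channels * kernel_size))
        self.params["W"] = rng.normal(0.0, scale, (out_channels, in_channels, kernel_size))
        self.params["b"] = np.zeros(out_channels)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, L = x.shape
        if C != self.in_channels:
            raise ConfigurationError(
                f"Conv1d expected {self.in_channels} channels, got {C}"
            )
        if self.padding == "same":
            left, right = _same_padding(L, self.kernel_size, self.stride)
        else:
            left = right = 0
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        Lp = xp.shape[2]
        L_out = (Lp - self.kernel_size) // self.stride + 1
        W = self.params["W"]
        y = np.zeros((B, self.out_channels, L_out))
        for j in range(self.kernel_size):
            xs = xp[:, :, j : j + self.stride * L_out : self.stride]
            y += np.einsum("oc,bcl->bol", W[:, :, j], xs, optimize=True)
        y += self.params["b"][None, :, None]
        self._cache = (xp, left, L, L_out)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, left, L, L_out = self._cache
        W = self.params["W"]
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        for j in range(self.kernel_size):
            sl = slice(j, j + self.stride * L_out, self.stride)
            xs = xp[:, :, sl]
            dW[:, :, j] = np.einsum("bol,bcl->oc", dout, xs, optimize=True)
            dxp[:, :, sl] += np.einsum("oc,bol->bcl", W[:, :, j], dout, optimize=True)
        self.grads["W"] = dW
        self.grads["b"] = dout.sum(axis=(0, 2))
        return dxp[:, :, left : left + L]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) / std[None, :, None]
        self._cache = (xhat, std, x.shape[0] * x.shape[2])
        return self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std, n = self._cache
        gamma = self.params["gamma"]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dout.sum(axis=(0, 2))
        dxhat = dout * gamma[None, :, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        ) / std[None, :, None]
        # note: the two mean terms assume training-mode statistics
        return dx


class BatchNormFlat(Layer):
    """Batch normalization over (batch, features) — used in the shrinkage gate."""

    def __init__(self, features: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(features)
        self.params["beta"] = np.zeros(features)
        self.running_mean = np.zeros(features)
        self.running_var = np.ones(features)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training and x.shape[0] > 1:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        self._cache = (xhat, std, training and x.shape[0] > 1)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std, batch_stats = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=0)
        self.grads["beta"] = dout.sum(axis=0)
        dxhat = dout * self.params["gamma"]
        if not batch_stats:
            return dxhat / std
        return (
            dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)
        ) / std


class Dense(Layer):
    def __init__(
        self, in_features: int, out_features: int, rng: np.random.Generator | None = None
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.params["W"] = rng.normal(0.0, scale, (in_features, out_features))
        self.params["b"] = np.zeros(out_features)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["W"] = x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.alpha * dout)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._out * (1.0 - self._out)


class MaxPool1d(Layer):
    """Max pooling with window == stride; trailing remainder is dropped."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, L = x.shape
        L_out = L // self.pool
        xv = x[:, :, : L_out * self.pool].reshape(B, C, L_out, self.pool)
        self._argmax = xv.argmax(axis=3)
        self._shape = x.shape
        return xv.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        L_out = dout.shape[2]
        dx = np.zeros((B, C, L_out, self.pool))
        np.put_along_axis(dx, self._argmax[..., None], dout[..., None], axis=3)
        full = np.zeros((B, C, L))
        full[:, :, : L_out * self.pool] = dx.reshape(B, C, L_out * self.pool)
        return full


class GlobalAvgPool1d(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, :, None], self._L, axis=2) / self._L


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ConfigurationError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class ShrinkageGate(Layer):
    """Channel-wise learned soft-thresholding.

    For a feature map x (B, C, L): the per-channel mean absolute activation
    a_c is squeezed through a two-layer fully connected bottleneck (batch
    norm and rectifier in between); the second layer has one output per
    channel and a sigmoid, giving a scaling alpha_c in (0, 1). The channel
    threshold is tau_c = alpha_c * a_c — always inside [0, a_c] — and the
    output is soft_threshold(x, tau_c). The residual connection around this
    gate lives in the enclosing residual unit.
    """

    def __init__(
        self, channels: int, reduction: int = 4, rng: np.random.Generator | None = None
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.channels = channels
        self.fc1 = Dense(channels, hidden, rng)
        self.bn = BatchNormFlat(hidden)
        self.act = ReLU()
        self.fc2 = Dense(hidden, channels, rng)
        self.sublayers = [self.fc1, self.bn, self.act, self.fc2]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ConfigurationError(
                f"ShrinkageGate expected {self.channels} channels, got {x.shape[1]}"
            )
        a = np.abs(x).mean(axis=2)  # (B, C)
        h = self.fc1.forward(a, training)
        h = self.act.forward(self.bn.forward(h, training), training)
        s = self.fc2.forward(h, training)
        alpha = 1.0 / (1.0 + np.exp(-s))
        tau = alpha * a
        mask = np.abs(x) > tau[:, :, None]
        y = np.sign(x) * (np.abs(x) - tau[:, :, None]) * mask
        self._cache = (x, a, alpha, tau, mask)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, a, alpha, tau, mask = self._cache
        sign = np.sign(x)
        L = x.shape[2]
        dx = dout * mask
        dtau = -(dout * sign * mask).sum(axis=2)  # (B, C)
        dalpha = dtau * a
        da = dtau * alpha
        ds = dalpha * alpha * (1.0 - alpha)
        dh = self.fc2.backward(ds)
        dh = self.bn.backward(self.act.backward(dh))
        da = da + self.fc1.backward(dh)
        dx = dx + da[:, :, None] * sign / L
        return dx
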