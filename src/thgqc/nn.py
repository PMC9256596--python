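"""Minimal NumPy neural-network layers with backpropagation.

Supports exactly what the fully-convolutional classifier needs: stride-1
"same"-padded convolution, batch normalization with running statistics,
ReLU, 2x2 max pooling with floor division of odd extents, global average
pooling, and SGD with momentum. Activations are NHWC (batch, height,
width, channels); convolution is computed as a sum of k*k channel-mixing
matmuls over shifted views, which keeps the work in BLAS without
materializing im2col patch matrices. Float32 by default; float64 is
available for gradient checking.

This is not a general deep-learning framework; it is sized for small CPU
experiments and keeps the layer contracts simple and fully deterministic.
"""

from __future__ import annotations

from typing import Optional

import numpy as np


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int,
               dtype) -> np.ndarray:
    """He uniform variance scaling: U(-limit, limit), limit = sqrt(6/fan_in)."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: parameter/gradient dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 convolution with symmetric "same" zero padding (odd kernel).

    Weights are stored as (F, C, k, k) with He-uniform initialization over
    fan-in C*k*k; an optional L2 penalty on the kernel (not the bias)
    contributes ``l2 * sum(w**2)`` to the loss and ``2*l2*w`` to the
    gradient.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32,
                 l2: float = 0.0) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = kernel
        self.l2 = l2
        fan_in = in_channels * kernel * kernel
        self.params["w"] = he_uniform(rng, (out_channels, in_channels,
                                            kernel, kernel), fan_in, dtype)
        self.params["b"] = np.zeros(out_channels, dtype=dtype)
        self._xp: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        w = self.params["w"]
        k, p = self.k, self.k // 2
        b, h, wd, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        out = np.zeros((b, h, wd, w.shape[0]), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                out += xp[:, i:i + h, j:j + wd, :] @ w[:, :, i, j].T
        out += self.params["b"]
        self._xp = xp if train else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w = self.params["w"]
        k, p = self.k, self.k // 2
        b, h, wd, _ = dout.shape
        xp = self._xp
        dw = np.empty_like(w)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = xp[:, i:i + h, j:j + wd, :]
                dw[:, :, i, j] = np.tensordot(dout, xs,
                                              axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i:i + h, j:j + wd, :] += dout @ w[:, :, i, j]
        if self.l2:
            dw += (2.0 * self.l2) * w
        self.grads["w"] = dw
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        self._xp = None
        return dxp[:, p:p + h, p:p + wd, :] if p else dxp

    def l2_penalty(self) -> float:
        return float(self.l2 * np.sum(
            self.params["w"].astype(np.float64) ** 2
        ))


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (B, H, W) with running stats."""

    def __init__(self, channels: int, dtype=np.float32, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        g = self.params["gamma"]
        b = self.params["beta"]
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
            inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
            xhat = (x - mean.astype(x.dtype)) * inv
            self._cache = (xhat, inv)
            return g * xhat + b
        mean = self.running_mean.astype(x.dtype)
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).astype(x.dtype)
        return g * ((x - mean) * inv) + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        g = self.params["gamma"]
        n = dout.shape[0] * dout.shape[1] * dout.shape[2]
        dg = (dout * xhat).sum(axis=(0, 1, 2))
        db = dout.sum(axis=(0, 1, 2))
        self.grads["gamma"] = dg
        self.grads["beta"] = db
        dx = (g * inv / n) * (n * dout - db - xhat * dg)
        self._cache = None
        return dx.astype(dout.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; odd trailing row/column is dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        if h2 == 0 or w2 == 0:
            raise ValueError(f"input {h}x{w} too small for 2x2 pooling")
        xr = x[:, : 2 * h2, : 2 * w2, :].reshape(b, h2, 2, w2, 2, c)
        out = xr.max(axis=(2, 4))
        self._cache = (x.shape, xr, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xshape, xr, out = self._cache
        mask = xr == out[:, :, None, :, None, :]
        dx_r = mask * dout[:, :, None, :, None, :]
        # ties split the gradient equally (a valid subgradient)
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dx_r = dx_r / counts
        b, h, w, c = xshape
        h2, w2 = h // 2, w // 2
        dx = np.zeros(xshape, dtype=dout.dtype)
        dx[:, : 2 * h2, : 2 * w2, :] = dx_r.reshape(b, 2 * h2, 2 * w2, c)
        self._cache = None
        return dx


class GlobalAvgPool(Layer):
    """(B, H, W, C) -> (B, C): mean over the spatial extent."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        return np.broadcast_to(
            dout[:, None, None, :] / (h * w), self._shape
        ).astype(dout.dtype).copy()


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dL/dz)."""
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    loss = float(np.mean(
        np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    ))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz


class SGDMomentum:
    """SGD with classical momentum: v <- mu*v - lr*g; w <- w + v."""

    def __init__(self, layers: list[Layer], lr: float,
                 momentum: float = 0.9) -> None:
        self.layers = layers
        self.lr = lr
        self.momentum = momentum
        self.velocity = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in layers
        ]

    def step(self) -> None:
        for layer, vel in zip(self.layers, self.velocity):
            for key, w in layer.params.items():
                g = layer.grads[key]
                v = vel[key]
                v *= self.momentum
                v -= self.lr * g.astype(v.dtype)
                w += v
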