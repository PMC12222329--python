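"""Minimal NumPy neural-network layers with explicit reverse-mode backprop.

Layers operate on NCHW float32 tensors (dense layers on (N, D)).  Each layer
caches what its backward pass needs during ``forward`` and exposes
``params`` / ``grads`` dictionaries consumed by :class:`Adam`.  Weight arrays
are flagged for L2 decay; biases and batch-norm affine terms are not decayed.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: stateless layers leave ``params`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.decay: dict[str, bool] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """Kaiming initialisation for ReLU-family nonlinearities."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2D(Layer):
    """3x3-style convolution, stride 1, symmetric 'same' zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel_size
        fan_in = in_ch * kernel_size * kernel_size
        self.params = {
            "W": he_normal(rng, (out_ch, in_ch, kernel_size, kernel_size), fan_in),
            "b": np.zeros(out_ch, dtype=np.float32),
        }
        self.decay = {"W": True, "b": False}
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None
        # the input-layer conv never needs d(input); skipping its col2im
        # saves a quarter of the backward pass
        self.skip_input_grad = False

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        # x: (B, C, H, W); returns (B, C*k*k, H*W) via k*k shifted block
        # copies of the zero-padded input (cache-friendly, no transposes)
        b, c, h, w = x.shape
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((b, c, k, k, h, w), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i:i + h, j:j + w]
        return cols.reshape(b, c * k * k, h * w)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_ch:
            raise ValueError(
                f"expected (B,{self.in_ch},H,W) input, got {x.shape}"
            )
        b, _, h, w = x.shape
        cols = self._im2col(x, self.k)
        wmat = self.params["W"].reshape(self.out_ch, -1)
        out = np.matmul(wmat[None], cols) + self.params["b"][None, :, None]
        self._cols, self._in_shape = cols, x.shape
        return out.reshape(b, self.out_ch, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, _, h, w = self._in_shape
        k, p = self.k, self.k // 2
        dflat = dout.reshape(b, self.out_ch, h * w)
        dw = np.matmul(dflat, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.grads["W"] = dw.reshape(self.params["W"].shape)
        self.grads["b"] = dflat.sum(axis=(0, 2))
        if self.skip_input_grad:
            return np.zeros((b, self.in_ch, h, w), dtype=dout.dtype)
        wmat = self.params["W"].reshape(self.out_ch, -1)
        dcols = np.matmul(wmat.T[None], dflat).reshape(
            b, self.in_ch, k, k, h, w
        )
        dxp = np.zeros((b, self.in_ch, h + 2 * p, w + 2 * p),
                       dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
        return dxp[:, :, p:p + h, p:p + w]


class BatchNorm2D(Layer):
    """Per-channel batch normalisation with running statistics for eval."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.decay = {"gamma": False, "beta": False}
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        bta = self.params["beta"][None, :, None, None]
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, training)
        return g * xhat + bta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, training = self._cache
        g = self.params["gamma"]
        self.grads["gamma"] = np.sum(dout * xhat, axis=(0, 2, 3))
        self.grads["beta"] = np.sum(dout, axis=(0, 2, 3))
        scale = (g * inv)[None, :, None, None]
        if not training:
            return dout * scale
        dmean = dout.mean(axis=(0, 2, 3))[None, :, None, None]
        dproj = (dout * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return scale * (dout - dmean - xhat * dproj)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2D(Layer):
    """Non-overlapping max pooling (window = stride = ``size``)."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        s = self.size
        b, c, h, w = x.shape
        if h % s or w % s:
            raise ValueError(f"spatial dims {h}x{w} not divisible by pool {s}")
        xr = x.reshape(b, c, h // s, s, w // s, s)
        windows = xr.transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h // s, w // s, s * s
        )
        self._argmax = windows.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(
            windows, self._argmax[..., None], axis=-1
        )[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s = self.size
        b, c, h, w = self._in_shape
        dwin = np.zeros((b, c, h // s, w // s, s * s), dtype=dout.dtype)
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        return (
            dwin.reshape(b, c, h // s, w // s, s, s)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h, w)
        )


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (
            self.rng.random(x.shape) < keep
        ).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": he_normal(rng, (out_dim, in_dim), in_dim),
            "b": np.zeros(out_dim, dtype=np.float32),
        }
        self.decay = {"W": True, "b": False}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class Adam:
    """Adam with classic L2 regularisation added to the gradient of weights.

    Biases and batch-norm affine parameters are excluded from decay, matching
    common deep-learning practice.
    """

    def __init__(self, layers: list[Layer], lr: float = 1e-4,
                 weight_decay: float = 1e-5, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [
            {k: np.zeros_like(v) for k, v in l.params.items()}
            for l in self.layers
        ]
        self._v = [
            {k: np.zeros_like(v) for k, v in l.params.items()}
            for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for key, p in layer.params.items():
                g = layer.grads[key].astype(np.float32, copy=False)
                if self.wd and layer.decay.get(key, False):
                    g = g + self.wd * p
                m[key] = self.beta1 * m[key] + (1 - self.beta1) * g
                v[key] = self.beta2 * v[key] + (1 - self.beta2) * g * g
                p -= self.lr * (m[key] / b1c) / (np.sqrt(v[key] / b2c) + self.eps)


def softmax(scores: np.ndarray) -> np.ndarray:
    """Row-wise normalised exponential."""
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
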