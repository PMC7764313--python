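"""Minimal NumPy layer engine: forward and backward passes for the handful of
layer types the network needs (convolution via im2col, batch normalization,
ReLU, average pooling, linear), plus an SGD-with-momentum parameter container.

All activations are NCHW float32 arrays. Each layer caches what its backward
pass needs on ``forward(..., train=True)``; ``backward`` consumes the cache and
accumulates parameter gradients in ``layer.grads``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class ShapeError(ValueError):
    """Raised when an activation does not match a layer's expected shape."""


def _as4d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=DTYPE)
    if x.ndim == 3:  # single C,H,W map
        x = x[None]
    if x.ndim != 4:
        raise ShapeError(f"expected NCHW or CHW array, got shape {x.shape}")
    return x


def im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Unfold NCHW into (N, C*kh*kw, out_h*out_w) patch columns."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
        writeable=False,
    )
    return windows.reshape(n, c * kh * kw, oh * ow), oh, ow


def col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """Fold patch columns back, summing overlaps (adjoint of im2col)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return out


class Layer:
    """Base: parameters in ``params``, matching gradients in ``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = False, rng: np.random.Generator | None = None,
                 name: str = "conv"):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.name = name
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        # He initialization: appropriate for ReLU-preactivated inputs
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=(out_ch, in_ch, kernel, kernel)).astype(DTYPE)
        if bias:
            self.params["b"] = np.zeros(out_ch, dtype=DTYPE)

    def forward(self, x, train=False):
        x = _as4d(x)
        if x.shape[1] != self.in_ch:
            raise ShapeError(
                f"layer '{self.name}': expected {self.in_ch} input channels, got {x.shape[1]}")
        cols, oh, ow = im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        wmat = self.params["W"].reshape(self.out_ch, -1)
        out = np.einsum("of,nfp->nop", wmat, cols, optimize=True)
        if "b" in self.params:
            out += self.params["b"][None, :, None]
        if train:
            self._cache = (x.shape, cols)
        return out.reshape(x.shape[0], self.out_ch, oh, ow)

    def backward(self, grad):
        x_shape, cols = self._cache
        n = grad.shape[0]
        g = grad.reshape(n, self.out_ch, -1)
        wmat = self.params["W"].reshape(self.out_ch, -1)
        self.grads["W"] = np.einsum("nop,nfp->of", g, cols, optimize=True).reshape(
            self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = g.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", wmat, g, optimize=True)
        return col2im(dcols, x_shape, self.kernel, self.kernel, self.stride, self.pad)


class BatchNorm2d(Layer):
    """Per-channel normalization with learned scale/shift and running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x, train=False):
        x = _as4d(x)
        if x.shape[1] != self.channels:
            raise ShapeError(f"batch norm expected {self.channels} channels, got {x.shape[1]}")
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.params["gamma"][None, :, None, None] * xhat \
            + self.params["beta"][None, :, None, None]

    def backward(self, grad):
        xhat, inv = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.grads["gamma"] = (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = grad.sum(axis=(0, 2, 3))
        g = grad * self.params["gamma"][None, :, None, None]
        # standard batch-norm gradient w.r.t. input
        dx = (g - g.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (g * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx * inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=False):
        x = np.asarray(x, dtype=DTYPE)
        out = np.maximum(x, 0)
        if train:
            self._cache = x > 0
        return out

    def backward(self, grad):
        return grad * self._cache


class AvgPool2d(Layer):
    """Non-overlapping k×k average pooling (the network only uses 2×2)."""

    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x, train=False):
        x = _as4d(x)
        n, c, h, w = x.shape
        k = self.k
        if h % k or w % k:
            raise ShapeError(f"average pooling needs spatial size divisible by {k}, got {h}x{w}")
        out = x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))
        if train:
            self._cache = x.shape
        return out

    def backward(self, grad):
        n, c, h, w = self._cache
        k = self.k
        g = np.repeat(np.repeat(grad, k, axis=2), k, axis=3) / (k * k)
        return g.astype(DTYPE)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        x = _as4d(x)
        if train:
            self._cache = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._cache
        return (np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)).astype(DTYPE)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / in_features),
                                      size=(out_features, in_features)).astype(DTYPE)
        if bias:
            self.params["b"] = np.zeros(out_features, dtype=DTYPE)

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=DTYPE)
        if train:
            self._cache = x
        out = x @ self.params["W"].T
        if "b" in self.params:
            out += self.params["b"]
        return out

    def backward(self, grad):
        x = self._cache
        self.grads["W"] = grad.T @ x
        if "b" in self.params:
            self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"]


class SGDMomentum:
    """Classic momentum SGD with decoupled-from-nothing L2 weight decay
    (decay is added to the gradient, as in standard SGD implementations)."""

    def __init__(self, layers, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.layers = [l for l in layers if l.params]
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        for layer, vel in zip(self.layers, self.velocity):
            for k, p in layer.params.items():
                g = layer.grads[k]
                if self.weight_decay and k not in ("beta", "b"):
                    g = g + self.weight_decay * p
                vel[k] = self.momentum * vel[k] - self.lr * g
                p += vel[k]
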