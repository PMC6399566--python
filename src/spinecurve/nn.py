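"""Minimal CPU neural-network layers with explicit backprop.

Just enough machinery for encoder-decoder segmentation networks on
small grayscale chips: 3x3 same-padded convolution (im2col + BLAS),
batch normalisation, ReLU, 2x2 max-pooling, 2x2 stride-2 transposed
convolution, channel concatenation, a sigmoid head, mean-squared-error
loss and Adam.  Tensors are NCHW float32.  Every layer implements
``forward(x, train)`` and ``backward(grad)``; parameters are shared
mutable ``Param`` objects collected by the optimiser.

This is a deliberate from-scratch implementation: the package has no
GPU/framework dependency, and the networks involved are small enough
that BLAS-backed matmuls keep desk-scale training in seconds to
minutes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2D", "BatchNorm2D", "ReLU", "Sigmoid", "MaxPool2x2",
           "ConvTranspose2x2", "Sequential", "Adam", "mse_loss", "mse_grad"]

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patches with same-padding for odd k."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


def _col2im(cols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    n, c, h, w = shape
    p = k // 2
    out = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
    cols = cols.reshape(n, h, w, c, k, k)
    for di in range(k):
        for dj in range(k):
            out[:, :, di : di + h, dj : dj + w] += cols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return out[:, :, p : p + h, p : p + w]


class Conv2D(Layer):
    """k x k convolution, stride 1, same padding, with bias."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * k * k
        scale = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU stacks
        self.W = Param(rng.normal(0, scale, size=(out_ch, in_ch, k, k)))
        self.b = Param(np.zeros(out_ch))
        self.k = k
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        n, c, h, w = x.shape
        self._xshape = x.shape
        self._cols = _im2col(x.astype(DTYPE, copy=False), self.k)
        wmat = self.W.value.reshape(self.out_ch, -1)
        y = self._cols @ wmat.T + self.b.value
        return y.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, _, h, w = self._xshape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch).astype(DTYPE, copy=False)
        self.W.grad += (g.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += g.sum(axis=0)
        gcols = g @ self.W.value.reshape(self.out_ch, -1)
        return _col2im(gcols, self._xshape, self.k)


class BatchNorm2D(Layer):
    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._std = std
        self._train = train
        return self.gamma.value[None, :, None, None] * self._xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        g = self.gamma.value[None, :, None, None]
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gx_hat = grad * g
        if not self._train:
            return gx_hat / self._std[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        sum_g = gx_hat.sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        sum_gx = (gx_hat * self._xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        return (gx_hat - sum_g / m - self._xhat * sum_gx / m) / self._std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class MaxPool2x2(Layer):
    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._xshape = x.shape
        return flat.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self._xshape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(out, self._arg[..., None], grad[..., None].astype(DTYPE), axis=-1)
        return out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (non-overlapping upsample)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_ch)
        self.W = Param(rng.normal(0, scale, size=(in_ch, out_ch, 2, 2)))
        self.b = Param(np.zeros(out_ch))
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x.astype(DTYPE, copy=False)
        n, c, h, w = x.shape
        # y[n, o, 2i+di, 2j+dj] = sum_c x[n, c, i, j] W[c, o, di, dj]
        y = np.einsum("nchw,codk->nohwdk", self._x, self.W.value, optimize=True)
        y = y.transpose(0, 1, 2, 4, 3, 5).reshape(n, self.out_ch, 2 * h, 2 * w)
        return y + self.b.value[None, :, None, None]

    def backward(self, grad):
        n, o, H, Wd = grad.shape
        g = grad.reshape(n, o, H // 2, 2, Wd // 2, 2).transpose(0, 1, 2, 4, 3, 5).astype(DTYPE, copy=False)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        self.W.grad += np.einsum("nchw,nohwdk->codk", self._x, g, optimize=True)
        return np.einsum("nohwdk,codk->nchw", g, self.W.value, optimize=True)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Adam:
    """Adaptive-moment optimiser (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Param], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared error over all elements of the batch."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    d = pred.astype(np.float64) - truth.astype(np.float64)
    return float(np.mean(d * d))


def mse_grad(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    return (2.0 / pred.size) * (pred - truth).astype(DTYPE)
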