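"""Minimal 3D neural-network layers with explicit forward/backward passes.

All layers operate on float32 tensors of shape (B, C, Z, Y, X). Each layer
caches what its backward pass needs during ``forward`` and releases it after
``backward``. Parameters and their gradients are exposed through
``params()`` as :class:`Param` objects so an optimizer can update them in
place. Convolutions use im2col + matmul; the col2im scatter in the backward
pass is expressed as 27 shifted slice-adds, which is what keeps pure-numpy
training of the small networks used here fast enough for CPU work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Layer", "Conv3d", "InstanceNorm3d", "LeakyReLU",
           "MaxPool3d", "Upsample3d"]


@dataclass
class Param:
    """A trainable tensor with its gradient and optimizer state slot."""

    name: str
    value: np.ndarray
    grad: np.ndarray = field(default=None)
    momentum: np.ndarray = field(default=None, repr=False)

    def zero_grad(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    __call__ = forward


class Conv3d(Layer):
    """3D convolution, stride 1, 'same' padding for odd kernels."""

    def __init__(self, cin: int, cout: int, ksize: int = 3,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        if ksize % 2 == 0:
            raise ValueError("only odd kernel sizes are supported")
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k = cin, cout, ksize
        fan_in = cin * ksize**3
        scale = np.sqrt(2.0 / fan_in)  # He init for (leaky) ReLU nets
        w = rng.normal(0.0, scale, size=(cout, cin, ksize, ksize, ksize))
        self.weight = Param(f"{name}.weight", w.astype(np.float32))
        self.bias = Param(f"{name}.bias", np.zeros(cout, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def _im2col(self, xp, shape):
        """Channels-major column matrix (cin*k^3, B*D*H*W); row ci*k^3 + o
        matches the flattened weight layout, so conv is a single GEMM."""
        b, c, d, h, w = shape
        k = self.k
        cols = np.empty((c, k**3, b * d * h * w), dtype=xp.dtype)
        o = 0
        for a in range(k):
            for bb in range(k):
                for cc in range(k):
                    xs = xp[:, :, a:a + d, bb:bb + h, cc:cc + w]
                    cols[:, o] = xs.transpose(1, 0, 2, 3, 4).reshape(c, -1)
                    o += 1
        return cols.reshape(c * k**3, -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        b, c, d, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        cols = self._im2col(xp, x.shape)
        wm = self.weight.value.reshape(self.cout, -1).astype(cols.dtype,
                                                             copy=False)
        out = (wm @ cols).reshape(self.cout, b, d, h, w)
        self._cache = (xp, x.shape)
        return (out.transpose(1, 0, 2, 3, 4)
                + self.bias.value.reshape(1, -1, 1, 1, 1))

    __call__ = forward

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xp, xshape = self._cache
        self._cache = None
        b, c, d, h, w = xshape
        k, p = self.k, self.k // 2
        self.bias.grad += gout.sum(axis=(0, 2, 3, 4))
        gt = np.ascontiguousarray(gout.transpose(1, 0, 2, 3, 4)).reshape(
            self.cout, -1)
        cols = self._im2col(xp, xshape)
        self.weight.grad += (gt @ cols.T).reshape(self.weight.value.shape)
        wm = self.weight.value.reshape(self.cout, -1).astype(gt.dtype,
                                                             copy=False)
        gcols = (wm.T @ gt).reshape(c, k**3, b, d, h, w)
        gx_pad = np.zeros_like(xp)
        o = 0
        for a in range(k):
            for bb in range(k):
                for cc in range(k):
                    gx_pad[:, :, a:a + d, bb:bb + h, cc:cc + w] += \
                        gcols[:, o].transpose(1, 0, 2, 3, 4)
                    o += 1
        if p == 0:
            return gx_pad
        return gx_pad[:, :, p:-p, p:-p, p:-p]


class InstanceNorm3d(Layer):
    """Normalize each (sample, channel) over its spatial extent; affine."""

    def __init__(self, channels: int, eps: float = 1e-5, name: str = "inorm"):
        self.eps = eps
        self.gamma = Param(f"{name}.gamma", np.ones(channels, dtype=np.float32))
        self.beta = Param(f"{name}.beta", np.zeros(channels, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (2, 3, 4)
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        g = self.gamma.value.reshape(1, -1, 1, 1, 1)
        self._cache = (xhat, inv)
        return g * xhat + self.beta.value.reshape(1, -1, 1, 1, 1)

    __call__ = forward

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        axes = (2, 3, 4)
        n = np.prod([xhat.shape[a] for a in axes])
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3, 4))
        self.beta.grad += gout.sum(axis=(0, 2, 3, 4))
        g = self.gamma.value.reshape(1, -1, 1, 1, 1)
        gxhat = gout * g
        # standard normalization backward per (b, c)
        gx = (gxhat - gxhat.mean(axis=axes, keepdims=True)
              - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)) * inv
        return gx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    __call__ = forward

    def backward(self, gout: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, gout, self.slope * gout)


class MaxPool3d(Layer):
    """2x2x2 max pooling; input spatial dims must be even."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x pooling")
        xr = x.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            b, c, d // 2, h // 2, w // 2, 8)
        arg = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, x.shape)
        return out

    __call__ = forward

    def backward(self, gout: np.ndarray) -> np.ndarray:
        arg, xshape = self._cache
        self._cache = None
        b, c, d, h, w = xshape
        gr = np.zeros((b, c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(gr, arg[..., None], gout[..., None], axis=-1)
        gr = gr.reshape(b, c, d // 2, h // 2, w // 2, 2, 2, 2)
        return gr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(b, c, d, h, w)


class Upsample3d(Layer):
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    __call__ = forward

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, c, d, h, w = gout.shape
        gr = gout.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
        return gr.sum(axis=(3, 5, 7))
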