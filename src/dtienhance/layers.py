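"""Minimal 3D convolutional layer stack with manual backpropagation.

All layers operate on arrays shaped (N, C, D, H, W) in float64 and
implement ``forward(x)`` / ``backward(grad_out)``; parameters and their
gradients are exposed through ``params()`` as named (value, grad) pairs
so one Adam optimizer can drive any composite model.  Only the pieces
needed by the encoder-decoder architecture are provided: same-shape
dilated 3x3x3 convolutions, 2x max pooling, stride-2 transposed
convolutions, instance normalization, ReLU and 1x1x1 projections.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "Conv3d",
    "ConvTranspose3d",
    "MaxPool3d",
    "InstanceNorm3d",
    "ReLU",
    "Adam",
]


class Layer:
    def params(self) -> List[Tuple[str, np.ndarray, np.ndarray]]:
        return []

    def zero_grad(self):
        for _, _, g in self.params():
            g[...] = 0.0


class Conv3d(Layer):
    """3D convolution, stride 1, odd kernel, shape-preserving padding
    (padding = dilation * (k - 1) / 2)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, dilation: int = 1,
                 rng: np.random.Generator = None, name: str = "conv",
                 bias: bool = True):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.dil = kernel, dilation
        self.pad = dilation * (kernel - 1) // 2
        fan_in = in_ch * kernel**3
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        rng = rng or np.random.default_rng(0)
        # weights stored per-tap: (k^3, out_ch, in_ch)
        self.w = rng.normal(0.0, std, (kernel**3, out_ch, in_ch))
        self.has_bias = bias  # omit when a normalization layer follows
        self.b = np.zeros(out_ch)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.name = name
        self._taps = [
            (a, b_, c)
            for a in range(kernel)
            for b_ in range(kernel)
            for c in range(kernel)
        ]

    def params(self):
        out = [(f"{self.name}.w", self.w, self.gw)]
        if self.has_bias:
            out.append((f"{self.name}.b", self.b, self.gb))
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, D, H, W = x.shape
        p, d = self.pad, self.dil
        xp = np.zeros((N, C, D + 2 * p, H + 2 * p, W + 2 * p))
        xp[:, :, p:-p or None, p:-p or None, p:-p or None] = x
        self._xp_shape = xp.shape
        self._x_slices = []
        V = D * H * W
        y = np.zeros((N, self.out_ch, V))
        for t, (a, b_, c) in enumerate(self._taps):
            xs = xp[:, :, a * d:a * d + D, b_ * d:b_ * d + H, c * d:c * d + W]
            xs = np.ascontiguousarray(xs).reshape(N, C, V)
            self._x_slices.append(xs)
            y += np.matmul(self.w[t], xs)  # (out,in) @ (N,in,V) -> (N,out,V)
        y += self.b[None, :, None]
        self._out_spatial = (D, H, W)
        return y.reshape(N, self.out_ch, D, H, W)

    def backward(self, g: np.ndarray) -> np.ndarray:
        N = g.shape[0]
        D, H, W = self._out_spatial
        V = D * H * W
        gf = g.reshape(N, self.out_ch, V)
        self.gb += gf.sum(axis=(0, 2))
        p, d = self.pad, self.dil
        gxp = np.zeros(self._xp_shape)
        wT = self.w.transpose(0, 2, 1)  # (taps, in, out)
        for t, (a, b_, c) in enumerate(self._taps):
            xs = self._x_slices[t]  # (N, in, V)
            self.gw[t] += np.einsum("nov,niv->oi", gf, xs, optimize=True)
            gx = np.matmul(wT[t], gf)  # (N, in, V)
            gxp[:, :, a * d:a * d + D, b_ * d:b_ * d + H, c * d:c * d + W] += (
                gx.reshape(N, self.in_ch, D, H, W)
            )
        self._x_slices = None
        return gxp[:, :, p:-p or None, p:-p or None, p:-p or None].copy()


class ConvTranspose3d(Layer):
    """Transposed 3D convolution with kernel 2 and stride 2 (exact 2x
    upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator = None,
                 name: str = "convT"):
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch
        std = np.sqrt(2.0 / fan_in)
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, std, (8, out_ch, in_ch))  # one (out,in) per corner
        self.b = np.zeros(out_ch)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.name = name
        self._taps = [(a, b_, c) for a in range(2) for b_ in range(2) for c in range(2)]

    def params(self):
        return [(f"{self.name}.w", self.w, self.gw), (f"{self.name}.b", self.b, self.gb)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, D, H, W = x.shape
        self._x = x.reshape(N, C, D * H * W)
        self._in_spatial = (D, H, W)
        y = np.zeros((N, self.out_ch, 2 * D, 2 * H, 2 * W))
        for t, (a, b_, c) in enumerate(self._taps):
            yt = np.matmul(self.w[t], self._x)  # (N, out, V)
            y[:, :, a::2, b_::2, c::2] = yt.reshape(N, self.out_ch, D, H, W)
        y += self.b[None, :, None, None, None]
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        N = g.shape[0]
        D, H, W = self._in_spatial
        self.gb += g.sum(axis=(0, 2, 3, 4))
        gx = np.zeros((N, self.in_ch, D * H * W))
        for t, (a, b_, c) in enumerate(self._taps):
            gt = np.ascontiguousarray(g[:, :, a::2, b_::2, c::2]).reshape(
                N, self.out_ch, D * H * W
            )
            self.gw[t] += np.einsum("nov,niv->oi", gt, self._x, optimize=True)
            gx += np.matmul(self.w[t].T, gt)
        self._x = None
        return gx.reshape(N, self.in_ch, D, H, W)


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2; input spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, D, H, W = x.shape
        xr = x.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            N, C, D // 2, H // 2, W // 2, 8
        )
        self._arg = np.argmax(xr, axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        N, C, D, H, W = self._in_shape
        gr = np.zeros((N, C, D // 2, H // 2, W // 2, 8))
        np.put_along_axis(gr, self._arg[..., None], g[..., None], axis=-1)
        gr = gr.reshape(N, C, D // 2, H // 2, W // 2, 2, 2, 2)
        gr = gr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(N, C, D, H, W)
        return gr


class InstanceNorm3d(Layer):
    """Per-sample, per-channel normalization over the spatial axes
    (no affine parameters)."""

    eps = 1e-5

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] * x.shape[3] * x.shape[4] == 1:
            # normalization over a single voxel is undefined (and would
            # zero the activation); pass through instead
            self._identity = True
            return x
        self._identity = False
        ax = (2, 3, 4)
        self._mu = x.mean(axis=ax, keepdims=True)
        self._var = x.var(axis=ax, keepdims=True)
        self._std = np.sqrt(self._var + self.eps)
        self._y = (x - self._mu) / self._std
        return self._y

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._identity:
            return g
        ax = (2, 3, 4)
        gm = g.mean(axis=ax, keepdims=True)
        gym = (g * self._y).mean(axis=ax, keepdims=True)
        gx = (g - gm - self._y * gym) / self._std
        self._y = None
        return gx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Adam:
    """Adam optimizer over a flat list of (name, value, grad) entries."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.entries = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(v) for _, v, _ in self.entries]
        self.v = [np.zeros_like(v) for _, v, _ in self.entries]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (name, val, grad), m, v in zip(self.entries, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * grad
            v *= self.b2
            v += (1 - self.b2) * grad * grad
            val -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for _, _, g in self.entries:
            g[...] = 0.0
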