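"""Patch-to-patch 3D encoder-decoder for tensor-field regression.

The architecture maps an 8-channel input patch (T1, b0, six
diffusion-weighted channels) to the 6 tensor coefficients at the same
spatial resolution: four encoder blocks of two dilated (d=2), stride-1
3x3x3 convolutions at widths 32/64/128/256, each followed by 2x max
pooling; a 512-filter bottleneck convolution; four decoder blocks of a
stride-2 transposed convolution, concatenation of the matching encoder
output and a 3x3x3 convolution; and a linear 1x1x1 regression head.
``width_scale`` shrinks every width proportionally so the same
architecture trains in minutes on a CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .layers import (
    Adam,
    Conv3d,
    ConvTranspose3d,
    InstanceNorm3d,
    MaxPool3d,
    ReLU,
)

__all__ = ["NetworkConfig", "UNet3D", "build_model", "count_parameters"]

N_LEVELS = 4
DOWN_FACTOR = 2**N_LEVELS  # input spatial dims must divide this


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 8
    out_channels: int = 6
    encoder_widths: Tuple[int, int, int, int] = (32, 64, 128, 256)
    bottleneck_width: int = 512
    dilation: int = 2
    width_scale: float = 1.0
    use_norm: bool = True  # instance normalization after each convolution
    seed: int = 0

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        w = self.encoder_widths
        if len(w) != N_LEVELS or any(a >= b for a, b in zip(w, w[1:])):
            raise ValueError("encoder_widths must be 4 strictly increasing counts")
        if self.bottleneck_width < w[-1]:
            raise ValueError("bottleneck_width must be >= last encoder width")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")

    @property
    def scaled_widths(self) -> Tuple[int, ...]:
        return tuple(max(1, round(w * self.width_scale)) for w in self.encoder_widths)

    @property
    def scaled_bottleneck(self) -> int:
        return max(1, round(self.bottleneck_width * self.width_scale))

    def to_dict(self) -> Dict:
        return {
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "encoder_widths": list(self.encoder_widths),
            "bottleneck_width": self.bottleneck_width,
            "dilation": self.dilation,
            "width_scale": self.width_scale,
            "use_norm": self.use_norm,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "NetworkConfig":
        d = dict(d)
        d["encoder_widths"] = tuple(d["encoder_widths"])
        return cls(**d)


class _ConvBlock:
    """conv [-> IN] -> ReLU, repeated ``n_convs`` times."""

    def __init__(self, chans: List[Tuple[int, int]], dilation, rng, name,
                 use_norm: bool = True):
        self.layers = []
        for i, (ci, co) in enumerate(chans):
            self.layers.append(
                Conv3d(ci, co, kernel=3, dilation=dilation, rng=rng,
                       name=f"{name}.conv{i}", bias=not use_norm)
            )
            if use_norm:
                self.layers.append(InstanceNorm3d())
            self.layers.append(ReLU())

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g

    def params(self):
        out = []
        for lay in self.layers:
            out += lay.params()
        return out


class UNet3D:
    """Hand-wired encoder-decoder; see module docstring for topology."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.scaled_widths
        bw = config.scaled_bottleneck
        d = config.dilation

        self.enc = []
        cin = config.in_channels
        for i, wi in enumerate(w):
            self.enc.append(
                _ConvBlock([(cin, wi), (wi, wi)], dilation=d, rng=rng,
                           name=f"enc{i}", use_norm=config.use_norm)
            )
            cin = wi
        self.pools = [MaxPool3d() for _ in range(N_LEVELS)]
        self.bottleneck = _ConvBlock([(w[-1], bw)], dilation=1, rng=rng,
                                     name="bneck", use_norm=config.use_norm)

        self.ups: List[ConvTranspose3d] = []
        self.dec: List[_ConvBlock] = []
        cin = bw
        for i in reversed(range(N_LEVELS)):
            self.ups.append(ConvTranspose3d(cin, w[i], rng=rng, name=f"up{i}"))
            self.dec.append(
                _ConvBlock([(2 * w[i], w[i])], dilation=1, rng=rng,
                           name=f"dec{i}", use_norm=config.use_norm)
            )
            cin = w[i]
        self.head = Conv3d(w[0], config.out_channels, kernel=1, dilation=1, rng=rng,
                           name="head")

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, D, H, W), got {x.shape}"
            )
        if any(s % DOWN_FACTOR for s in x.shape[2:]):
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by {DOWN_FACTOR}"
            )
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_chans = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_chans.append(skip.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = dec.forward(x)
        return self.head.forward(x)

    def backward(self, g: np.ndarray) -> None:
        """Accumulate parameter gradients; returns nothing (input grads
        are discarded at the first layer)."""
        g = self.head.backward(g)
        skip_grads = []
        # walk decoder in reverse build order
        for i in reversed(range(N_LEVELS)):
            g = self.dec[i].backward(g)
            sc = self._skip_chans[i]
            g, gskip = g[:, :-sc], g[:, -sc:]
            skip_grads.append(gskip)
            g = self.ups[i].backward(g)
        g = self.bottleneck.backward(g)
        skip_grads = skip_grads[::-1]  # now indexed like self.dec (deep->shallow)
        for lvl in reversed(range(N_LEVELS)):
            g = self.pools[lvl].backward(g)
            # decoder level lvl consumed the skip from encoder level lvl:
            # self.dec[j] with j = N_LEVELS-1-lvl
            g = g + skip_grads[N_LEVELS - 1 - lvl]
            g = self.enc[lvl].backward(g)

    # -- parameters ----------------------------------------------------------

    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for up in self.ups:
            out += up.params()
        for dec in self.dec:
            out += dec.params()
        out += self.head.params()
        return out

    def zero_grad(self):
        for _, _, g in self.params():
            g[...] = 0.0

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: val.copy() for name, val, _ in self.params()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for name, val, _ in self.params():
            val[...] = state[name]

    def make_optimizer(self, lr: float = 1e-4) -> Adam:
        return Adam(self.params(), lr=lr)


def build_model(config: NetworkConfig) -> UNet3D:
    """Construct the network with deterministic seeded initialization."""
    return UNet3D(config)


def count_parameters(model: UNet3D) -> int:
    """Total trainable scalar parameters."""
    return int(sum(val.size for _, val, _ in model.params()))
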