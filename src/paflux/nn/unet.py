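"""Encoder-decoder ("U") convolutional surrogate.

Maps the 3-channel optical stack (mu_a, mu_s, g) to the 1-channel
log-compressed initial pressure. Four max-pooling downsamplings, channel
width doubling per level, concatenation skip connections, batch
normalization and leaky-rectifier activations, dropout after each decoder
block. Spatial dimensions must be divisible by 2^depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as F
from .autodiff import Tensor
from .modules import BatchNorm2d, Conv2d, Dropout, LeakyReLU, Module

__all__ = ["UNetConfig", "UNet"]


@dataclass(frozen=True)
class UNetConfig:
    in_channels: int = 3
    out_channels: int = 1
    depth: int = 4
    base_width: int = 8
    dropout: float = 0.5
    negative_slope: float = 0.01
    residual_skips: bool = False  # add instead of concatenate
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be at least 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def full_scale_unet_config(**overrides) -> UNetConfig:
    """Full-scale configuration (base width 64, the original convention)."""
    return UNetConfig(base_width=64, **overrides)


class _DoubleConv(Module):
    def __init__(self, cin: int, cout: int, slope: float,
                 rng: np.random.Generator, dtype):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(cout, dtype=dtype)
        self.act1 = LeakyReLU(slope)
        self.conv2 = Conv2d(cout, cout, 3, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(cout, dtype=dtype)
        self.act2 = LeakyReLU(slope)

    def forward(self, x: Tensor) -> Tensor:
        x = self.act1(self.bn1(self.conv1(x)))
        return self.act2(self.bn2(self.conv2(x)))


class UNet(Module):
    def __init__(self, config: UNetConfig | None = None):
        super().__init__()
        self.config = config or UNetConfig()
        cfg = self.config
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(cfg.seed)
        widths = [cfg.base_width * 2**i for i in range(cfg.depth + 1)]

        self.enc = []
        cin = cfg.in_channels
        for i, width in enumerate(widths[:-1]):
            block = _DoubleConv(cin, width, cfg.negative_slope, rng, dtype)
            setattr(self, f"enc{i}", block)
            self.enc.append(block)
            cin = width
        self.bottleneck = _DoubleConv(widths[-2], widths[-1],
                                      cfg.negative_slope, rng, dtype)

        self.up = []
        self.dec = []
        self.drop = []
        for i in reversed(range(cfg.depth)):
            upconv = Conv2d(widths[i + 1], widths[i], 3, rng=rng, dtype=dtype)
            skip_in = widths[i] if cfg.residual_skips else 2 * widths[i]
            block = _DoubleConv(skip_in, widths[i], cfg.negative_slope, rng, dtype)
            drop = Dropout(cfg.dropout, seed=cfg.seed + 100 + i)
            setattr(self, f"up{i}", upconv)
            setattr(self, f"dec{i}", block)
            setattr(self, f"drop{i}", drop)
            self.up.append(upconv)
            self.dec.append(block)
            self.drop.append(drop)
        self.head = Conv2d(widths[0], cfg.out_channels, 1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        h, w = x.shape[2], x.shape[3]
        div = 2**cfg.depth
        if h % div or w % div:
            raise ValueError(
                f"spatial dimensions ({h}, {w}) must be divisible by 2^{cfg.depth}"
            )
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = F.maxpool2(x)
        x = self.bottleneck(x)
        for upconv, block, drop, skip in zip(self.up, self.dec, self.drop,
                                             reversed(skips)):
            x = upconv(F.upsample2(x))
            x = (x + skip) if cfg.residual_skips else F.concat([skip, x], axis=1)
            x = drop(block(x))
        return self.head(x)
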