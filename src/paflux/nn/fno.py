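"""Fourier Neural Operator surrogate.

A pointwise linear layer lifts the 3-channel optical stack into a latent
space; four Fourier layers follow, each with two parallel paths — a
mode-truncated spectral convolution for global, smooth structure and a
local convolution for high-frequency features. The paths are concatenated
along channels, projected back to the latent width, and passed through a
Gaussian-error activation. Two pointwise layers project to the 1-channel
log-compressed initial pressure.

Because the spectral weights act on a fixed set of low frequencies, one
trained model can be applied at any grid resolution that resolves those
modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as F
from .autodiff import Tensor
from .modules import Conv2d, GELU, Module, SpectralConv2d

__all__ = ["FNOConfig", "FNO"]


@dataclass(frozen=True)
class FNOConfig:
    in_channels: int = 3
    out_channels: int = 1
    width: int = 10  # latent channel count
    n_layers: int = 4
    modes: int = 12  # retained low frequencies per spatial dimension
    local_kernel: int = 1  # 1 (pointwise) or 3 (spatial) local path
    additive_paths: bool = False  # add paths instead of concatenating
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("latent width must be at least 1")
        if self.modes < 1:
            raise ValueError("retained mode count must be at least 1")
        if self.local_kernel not in (1, 3):
            raise ValueError("local path kernel must be 1 or 3")


def full_scale_fno_config(**overrides) -> FNOConfig:
    """Full-scale configuration: 128-dimensional latent space."""
    return FNOConfig(width=128, **overrides)


class _FourierLayer(Module):
    def __init__(self, width: int, modes: int, local_kernel: int,
                 additive: bool, rng: np.random.Generator, dtype):
        super().__init__()
        self.additive = additive
        self.spectral = SpectralConv2d(width, width, modes, rng=rng, dtype=dtype)
        self.local = Conv2d(width, width, local_kernel, rng=rng, dtype=dtype)
        if not additive:
            self.merge = Conv2d(2 * width, width, 1, rng=rng, dtype=dtype)
        self.act = GELU()

    def forward(self, x: Tensor) -> Tensor:
        a = self.spectral(x)
        b = self.local(x)
        if self.additive:
            return self.act(a + b)
        return self.act(self.merge(F.concat([a, b], axis=1)))


class FNO(Module):
    def __init__(self, config: FNOConfig | None = None):
        super().__init__()
        self.config = config or FNOConfig()
        cfg = self.config
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(cfg.seed)
        self.lift = Conv2d(cfg.in_channels, cfg.width, 1, rng=rng, dtype=dtype)
        self.layers = []
        for i in range(cfg.n_layers):
            layer = _FourierLayer(cfg.width, cfg.modes, cfg.local_kernel,
                                  cfg.additive_paths, rng, dtype)
            setattr(self, f"fourier{i}", layer)
            self.layers.append(layer)
        self.proj1 = Conv2d(cfg.width, cfg.width, 1, rng=rng, dtype=dtype)
        self.proj_act = GELU()
        self.proj2 = Conv2d(cfg.width, cfg.out_channels, 1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        h, w = x.shape[2], x.shape[3]
        if 2 * cfg.modes - 1 > min(h, w):
            raise ValueError(
                f"grid {h}x{w} cannot resolve {cfg.modes} retained modes"
            )
        x = self.lift(x)
        for layer in self.layers:
            x = layer(x)
        return self.proj2(self.proj_act(self.proj1(x)))
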