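"""Layer and container classes on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as F
from .autodiff import Tensor

__all__ = ["Parameter", "Module", "Conv2d", "BatchNorm2d", "Dropout",
           "LeakyReLU", "GELU", "SpectralConv2d", "Sequential"]


class Parameter(Tensor):
    """Learnable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class with automatic parameter/submodule registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        object.__setattr__(self, "training", True)
        for mod in self._modules.values():
            mod.train()
        return self

    def eval(self) -> "Module":
        object.__setattr__(self, "training", False)
        for mod in self._modules.values():
            mod.eval()
        return self

    # -- (de)serialization ------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {name}")
                params[name].data = value.astype(params[name].data.dtype, copy=True)
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown state entry {name}")

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield f"{prefix}{name}", getattr(self, name)
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix=f"{prefix}{name}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 convolution with 'same' padding for odd kernels by default."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int | None = None, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        self.padding = (k // 2) if padding is None else padding
        fan_in = in_channels * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            (rng.standard_normal((out_channels, in_channels, k, k)) * scale
             ).astype(dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps
        object.__setattr__(self, "_buffer_names", ("running_mean", "running_var"))

    def forward(self, x: Tensor) -> Tensor:
        return F.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training,
                             momentum=self.momentum, eps=self.eps)


class Dropout(Module):
    def __init__(self, p: float = 0.5, seed: int = 0):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        return F.dropout(x, self.p, self.rng, self.training)


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.01):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x: Tensor) -> Tensor:
        return F.leaky_relu(x, self.negative_slope)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.gelu(x)


class SpectralConv2d(Module):
    """Learnable mode-truncated spectral convolution (see autodiff)."""

    def __init__(self, in_channels: int, out_channels: int, modes: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.modes = modes
        m = 2 * modes - 1
        scale = 1.0 / (in_channels * out_channels)
        shape = (in_channels, out_channels, m, m)
        self.w_real = Parameter((scale * rng.standard_normal(shape)).astype(dtype))
        self.w_imag = Parameter((scale * rng.standard_normal(shape)).astype(dtype))

    def forward(self, x: Tensor) -> Tensor:
        return F.spectral_conv2d(x, self.w_real, self.w_imag, self.modes)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
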