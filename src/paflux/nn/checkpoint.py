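"""Single-file model checkpoints (.npz with a JSON header)."""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from .fno import FNO, FNOConfig
from .modules import Module
from .unet import UNet, UNetConfig

__all__ = ["save_checkpoint", "load_checkpoint", "build_model"]


def build_model(architecture: str, config: dict | None = None) -> Module:
    config = config or {}
    if architecture == "unet":
        return UNet(UNetConfig(**config))
    if architecture == "fno":
        return FNO(FNOConfig(**config))
    raise ValueError(f"unknown architecture {architecture!r}; expected unet or fno")


def save_checkpoint(path, model: Module, metadata: dict | None = None) -> None:
    if isinstance(model, UNet):
        tag = "unet"
    elif isinstance(model, FNO):
        tag = "fno"
    else:
        raise TypeError("model must be a UNet or FNO")
    header = {
        "architecture": tag,
        "config": asdict(model.config),
        "metadata": metadata or {},
    }
    state = {f"state/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, header=np.array(json.dumps(header)), **state)


def load_checkpoint(path) -> tuple[Module, dict]:
    """Rebuild the model and return it (eval mode) with its metadata."""
    with np.load(path, allow_pickle=False) as archive:
        header = json.loads(str(archive["header"]))
        state = {
            key[len("state/"):]: archive[key]
            for key in archive.files
            if key.startswith("state/")
        }
    model = build_model(header["architecture"], header["config"])
    model.load_state_dict(state)
    model.eval()
    return model, header["metadata"]
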