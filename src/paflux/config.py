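"""Pipeline configuration, seed derivation and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .grid import GridSpec, desk_grid
from .mc import IlluminationSpec, TransportConfig
from .tissue import GeometryConfig

__all__ = ["PipelineConfig", "RunManifest", "derive_seed",
           "desk_scale_config", "full_scale_config"]


def derive_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage, per-sample seed below 2^31."""
    digest = hashlib.blake2b(
        f"{master_seed}:{stage}:{index}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """Everything needed to generate a dataset and train the surrogates."""

    grid: GridSpec = field(default_factory=desk_grid)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    illumination: IlluminationSpec = field(default_factory=IlluminationSpec)
    transport: TransportConfig = field(default_factory=TransportConfig)
    wavelengths: tuple[float, ...] = (700.0, 750.0, 800.0, 850.0)
    n_samples: int = 100
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    master_seed: int = 0
    fixed_g: float | None = 0.0  # reduced-scattering adjustment target; None keeps per-pixel g
    fluence_scale: float | None = None  # None -> illuminated area (p0 ~ O(1))

    def __post_init__(self) -> None:
        if not self.wavelengths:
            raise ValueError("wavelength list must be nonempty")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    def stage_seed(self, stage: str, index: int = 0) -> int:
        return derive_seed(self.master_seed, stage, index)

    # -- YAML round trip --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "grid" in raw and isinstance(raw["grid"], dict):
            raw["grid"] = GridSpec(**raw["grid"])
        for key, typ in (("geometry", GeometryConfig),
                         ("illumination", IlluminationSpec),
                         ("transport", TransportConfig)):
            if key in raw and isinstance(raw[key], dict):
                sub = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw[key].items()
                }
                raw[key] = typ(**sub)
        for key in ("wavelengths", "split_fractions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def desk_scale_config(**overrides) -> PipelineConfig:
    """Reduced problem size for single-CPU runs: 64 x 128 grid, 100 samples,
    4 wavelengths, 10^6 photons."""
    return PipelineConfig(**overrides)


def full_scale_config(**overrides) -> PipelineConfig:
    """Full-scale study conditions: 128 x 256 grid at 0.15625 mm, 1100
    samples with a 770/110/220 split, 16 wavelengths (700-850 nm in 10 nm
    steps), 5 x 10^8 photons per map."""
    defaults = dict(
        grid=GridSpec(128, 256, 0.15625),
        wavelengths=tuple(float(w) for w in range(700, 851, 10)),
        n_samples=1100,
        split_fractions=(0.7, 0.1, 0.2),
        transport=TransportConfig(n_photons=500_000_000),
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


@dataclass
class RunManifest:
    """Reproducibility record: config hash, stage seeds and output digests."""

    config_hash: str
    master_seed: int
    version: str
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def record_output(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
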