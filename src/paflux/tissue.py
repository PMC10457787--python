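"""Virtual forearm tissue generation and optical-property assignment.

A sample is built in two steps: :func:`sample_forearm_geometry` draws a
randomized label map (skin band over soft background with embedded artery /
vein cross-sections), then :func:`assign_optical_properties` paints
per-pixel absorption, scattering and anisotropy maps for one wavelength
from a tissue library of chromophore mixtures and scattering power laws.

Vessel counts, radii and depths are drawn from uniform stand-in
distributions (the literature distributions behind real forearm atlases are
not reproduced here); every range is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import h5py
import numpy as np

from .grid import ARTERY, BACKGROUND, SKIN, VEIN, GridSpec, LabelMap, Vessel
from .spectra import chromophore_absorption

__all__ = [
    "TissueLibraryEntry",
    "GeometryConfig",
    "OpticalPropertyMap",
    "sample_forearm_geometry",
    "assign_optical_properties",
    "adjust_scattering_for_fixed_g",
    "sample_tissue_library",
    "blood_entry",
    "save_tissue_h5",
    "load_tissue_h5",
]


@dataclass(frozen=True)
class TissueLibraryEntry:
    """Optical recipe for one tissue class.

    ``chromophores`` lists (chromophore id, volume fraction) pairs; the
    absorption coefficient is the fraction-weighted sum of the packaged
    spectra. Scattering follows the power law
    mu_s(lambda) = mus_at_800 * (lambda / 800)^(-scatter_power).
    """

    label: int
    chromophores: tuple[tuple[str, float], ...]
    mus_at_800: float  # mm^-1
    scatter_power: float
    g: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.g < 1.0:
            raise ValueError("anisotropy g must lie in [0, 1)")
        if not self.mus_at_800 > 0:
            raise ValueError("scattering reference must be positive")
        if any(frac < 0 for _, frac in self.chromophores):
            raise ValueError("volume fractions must be nonnegative")

    def mu_a(self, wavelength: float) -> float:
        return sum(
            frac * chromophore_absorption(cid, wavelength)
            for cid, frac in self.chromophores
        )

    def mu_s(self, wavelength: float) -> float:
        return self.mus_at_800 * (wavelength / 800.0) ** (-self.scatter_power)


def blood_entry(label: int, oxygenation: float, blood_fraction: float = 1.0,
                mus_at_800: float = 70.0, scatter_power: float = 1.1,
                g: float = 0.99) -> TissueLibraryEntry:
    """Whole-blood recipe at the given oxygen saturation."""
    if not 0.0 <= oxygenation <= 1.0:
        raise ValueError("oxygenation must lie in [0, 1]")
    return TissueLibraryEntry(
        label=label,
        chromophores=(
            ("hbo2", blood_fraction * oxygenation),
            ("hb", blood_fraction * (1.0 - oxygenation)),
        ),
        mus_at_800=mus_at_800,
        scatter_power=scatter_power,
        g=g,
    )


def _check_range(name: str, rng: tuple[float, float], positive: bool = False) -> None:
    lo, hi = rng
    if lo > hi:
        raise ValueError(f"{name}: empty range [{lo}, {hi}]")
    if positive and lo <= 0:
        raise ValueError(f"{name}: values must be positive")


@dataclass(frozen=True)
class GeometryConfig:
    """Randomization ranges for forearm geometry and tissue composition."""

    seed: int = 0
    vessel_count: tuple[int, int] = (2, 6)
    vessel_radius_mm: tuple[float, float] = (0.5, 3.0)
    vessel_depth_mm: tuple[float, float] = (2.0, 15.0)
    skin_thickness_mm: tuple[float, float] = (0.5, 2.0)
    skin_undulation_mm: float = 0.0  # sinusoidal skin-boundary amplitude
    artery_oxygenation: tuple[float, float] = (0.8, 1.0)
    vein_oxygenation: tuple[float, float] = (0.4, 0.8)
    background_blood_fraction: tuple[float, float] = (0.01, 0.03)
    background_oxygenation: tuple[float, float] = (0.5, 0.9)
    skin_melanin_fraction: tuple[float, float] = (0.01, 0.04)

    def validate(self, grid: GridSpec) -> None:
        if self.vessel_count[0] > self.vessel_count[1] or self.vessel_count[0] < 0:
            raise ValueError("vessel_count: invalid range")
        _check_range("vessel_radius_mm", self.vessel_radius_mm, positive=True)
        _check_range("vessel_depth_mm", self.vessel_depth_mm)
        _check_range("skin_thickness_mm", self.skin_thickness_mm, positive=True)
        _check_range("artery_oxygenation", self.artery_oxygenation)
        _check_range("vein_oxygenation", self.vein_oxygenation)
        _check_range("background_blood_fraction", self.background_blood_fraction)
        _check_range("background_oxygenation", self.background_oxygenation)
        _check_range("skin_melanin_fraction", self.skin_melanin_fraction)
        if 2.0 * self.vessel_radius_mm[1] >= min(grid.depth_mm, grid.lateral_mm):
            raise ValueError("vessel radius range exceeds the grid extent")
        if self.vessel_radius_mm[0] + self.skin_thickness_mm[1] >= grid.depth_mm:
            raise ValueError("vessels cannot fit below the skin on this grid")


@dataclass
class OpticalPropertyMap:
    """Per-pixel absorption, scattering and anisotropy at one wavelength."""

    grid: GridSpec
    wavelength: float  # nm
    mu_a: np.ndarray  # mm^-1
    mu_s: np.ndarray  # mm^-1
    g: np.ndarray  # dimensionless

    def __post_init__(self) -> None:
        for name in ("mu_a", "mu_s", "g"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape does not match grid")

    def validate(self) -> None:
        if not np.all(self.mu_a > 0):
            raise ValueError("mu_a must be strictly positive everywhere")
        if not np.all(self.mu_s >= 0):
            raise ValueError("mu_s must be nonnegative")
        if not (np.all(self.g >= 0) and np.all(self.g < 1)):
            raise ValueError("g must lie in [0, 1)")

    def stacked(self) -> np.ndarray:
        """3-channel (mu_a, mu_s, g) stack — the network input layout."""
        return np.stack([self.mu_a, self.mu_s, self.g], axis=0)


def sample_forearm_geometry(config: GeometryConfig, grid: GridSpec,
                            max_tries: int = 500) -> LabelMap:
    """Draw a random forearm cross-section label map.

    Deterministic in (config, grid): the same seed reproduces the map
    bitwise. Vessels are non-overlapping circles strictly below the skin
    band; labels alternate artery / vein so arteries come with accompanying
    veins.
    """
    config.validate(grid)
    rng = np.random.default_rng(config.seed)
    labels = np.full(grid.shape, BACKGROUND, dtype=np.int8)
    vessel_ids = np.zeros(grid.shape, dtype=np.int16)

    thickness = rng.uniform(*config.skin_thickness_mm)
    skin_rows = math.ceil(thickness / grid.spacing)
    skin_rows = min(skin_rows, grid.n_depth - 1)
    x_centers = grid.lateral_centers()
    if config.skin_undulation_mm > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        period = rng.uniform(10.0, 30.0)  # mm
        boundary = thickness + config.skin_undulation_mm * np.sin(
            2.0 * np.pi * x_centers / period + phase
        )
        rows_per_col = np.ceil(np.maximum(boundary, grid.spacing) / grid.spacing)
        rows_per_col = np.clip(rows_per_col.astype(int), 1, grid.n_depth - 1)
        for col, rows in enumerate(rows_per_col):
            labels[:rows, col] = SKIN
        skin_max_mm = float(rows_per_col.max()) * grid.spacing
    else:
        labels[:skin_rows] = SKIN
        skin_max_mm = skin_rows * grid.spacing

    n_vessels = int(rng.integers(config.vessel_count[0], config.vessel_count[1] + 1))
    vessels: list[Vessel] = []
    zc = grid.depth_centers()[:, None]
    xc = x_centers[None, :]
    for k in range(n_vessels):
        label = ARTERY if k % 2 == 0 else VEIN
        oxy_range = (config.artery_oxygenation if label == ARTERY
                     else config.vein_oxygenation)
        placed = False
        for _ in range(max_tries):
            radius = rng.uniform(*config.vessel_radius_mm)
            lo = max(config.vessel_depth_mm[0], skin_max_mm + radius + grid.spacing)
            hi = min(config.vessel_depth_mm[1], grid.depth_mm - radius)
            if lo >= hi:
                continue
            cz = rng.uniform(lo, hi)
            cx = rng.uniform(radius, grid.lateral_mm - radius)
            clearance = grid.spacing
            if all(
                math.hypot(cz - v.center_depth, cx - v.center_lateral)
                > radius + v.radius + clearance
                for v in vessels
            ):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place vessel {k + 1}/{n_vessels} without overlap; "
                "loosen the geometry ranges"
            )
        oxygenation = rng.uniform(*oxy_range)
        vessels.append(Vessel(cz, cx, radius, label, oxygenation))
        mask = (zc - cz) ** 2 + (xc - cx) ** 2 <= radius**2
        labels[mask] = label
        vessel_ids[mask] = len(vessels)

    label_map = LabelMap(
        grid=grid,
        labels=labels,
        vessels=vessels,
        vessel_ids=vessel_ids,
        skin_rows=skin_rows if config.skin_undulation_mm == 0 else 0,
        seed=config.seed,
    )
    label_map.validate()
    return label_map


def sample_tissue_library(config: GeometryConfig, rng: np.random.Generator
                          ) -> dict[int, TissueLibraryEntry]:
    """Draw one concrete tissue library (class -> recipe) for a sample.

    Background is a weakly absorbing, water-rich mixture with a small
    perfused blood fraction; skin is melanin-dominated; the blood classes
    here are per-class fallbacks — per-vessel oxygenation painted by
    :func:`assign_optical_properties` overrides them.
    """
    bg_blood = rng.uniform(*config.background_blood_fraction)
    bg_oxy = rng.uniform(*config.background_oxygenation)
    melanin = rng.uniform(*config.skin_melanin_fraction)
    background = TissueLibraryEntry(
        label=BACKGROUND,
        chromophores=(
            ("hbo2", bg_blood * bg_oxy),
            ("hb", bg_blood * (1.0 - bg_oxy)),
            ("water", 0.68),
            ("fat", 0.10),
        ),
        mus_at_800=10.0,
        scatter_power=1.2,
        g=0.9,
    )
    skin = TissueLibraryEntry(
        label=SKIN,
        chromophores=(
            ("melanin", melanin),
            ("water", 0.50),
            ("hbo2", 0.002),
            ("hb", 0.002),
        ),
        mus_at_800=18.0,
        scatter_power=1.5,
        g=0.9,
    )
    artery = blood_entry(ARTERY, oxygenation=0.95)
    vein = blood_entry(VEIN, oxygenation=0.6)
    return {BACKGROUND: background, SKIN: skin, ARTERY: artery, VEIN: vein}


def assign_optical_properties(label_map: LabelMap, wavelength: float,
                              library: dict[int, TissueLibraryEntry],
                              ) -> OpticalPropertyMap:
    """Paint (mu_a, mu_s, g) maps for one wavelength.

    Every tissue class present in the label map must have a library entry.
    Vessel pixels are painted per vessel using the oxygenation stored in the
    vessel table, with the class entry supplying the scattering recipe.
    """
    present = set(np.unique(label_map.labels).tolist())
    missing = present - set(library)
    if missing:
        raise KeyError(f"no tissue library entry for labels {sorted(missing)}")

    mu_a = np.zeros(label_map.grid.shape)
    mu_s = np.zeros(label_map.grid.shape)
    g = np.zeros(label_map.grid.shape)
    for label in present:
        entry = library[label]
        mask = label_map.labels == label
        mu_a[mask] = entry.mu_a(wavelength)
        mu_s[mask] = entry.mu_s(wavelength)
        g[mask] = entry.g

    for vid, vessel in enumerate(label_map.vessels, start=1):
        mask = label_map.vessel_ids == vid
        if not mask.any():
            continue  # vessel fully occluded by a later one
        base = library[vessel.label]
        entry = blood_entry(
            vessel.label,
            oxygenation=vessel.oxygenation,
            mus_at_800=base.mus_at_800,
            scatter_power=base.scatter_power,
            g=base.g,
        )
        mu_a[mask] = entry.mu_a(wavelength)
        mu_s[mask] = entry.mu_s(wavelength)
        g[mask] = entry.g

    opt = OpticalPropertyMap(label_map.grid, wavelength, mu_a, mu_s, g)
    opt.validate()
    return opt


def adjust_scattering_for_fixed_g(opt: OpticalPropertyMap, g_fixed: float
                                  ) -> OpticalPropertyMap:
    """Substitute a single anisotropy while preserving mu_s' = mu_s (1 - g).

    This is the similarity-relation adjustment used when the transport code
    supports only one global g: the adjusted medium is equivalent in the
    diffusive regime (and may differ in the quasi-ballistic regime).
    """
    if not 0.0 <= g_fixed < 1.0:
        raise ValueError("g_fixed must lie in [0, 1)")
    mu_s_adj = opt.mu_s * (1.0 - opt.g) / (1.0 - g_fixed)
    return OpticalPropertyMap(
        grid=opt.grid,
        wavelength=opt.wavelength,
        mu_a=opt.mu_a.copy(),
        mu_s=mu_s_adj,
        g=np.full(opt.grid.shape, g_fixed),
    )


def save_tissue_h5(path, opt: OpticalPropertyMap,
                   label_map: LabelMap | None = None) -> None:
    """Write /labels, /mua, /mus, /g with spacing/wavelength/seed attributes."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("mua", data=opt.mu_a)
        fh.create_dataset("mus", data=opt.mu_s)
        fh.create_dataset("g", data=opt.g)
        if label_map is not None:
            fh.create_dataset("labels", data=label_map.labels)
            if label_map.seed is not None:
                fh.attrs["seed"] = label_map.seed
        fh.attrs["spacing_mm"] = opt.grid.spacing
        fh.attrs["wavelength_nm"] = opt.wavelength


def load_tissue_h5(path) -> tuple[OpticalPropertyMap, np.ndarray | None]:
    with h5py.File(path, "r") as fh:
        mu_a = fh["mua"][()]
        mu_s = fh["mus"][()]
        g = fh["g"][()]
        labels = fh["labels"][()] if "labels" in fh else None
        spacing = float(fh.attrs["spacing_mm"])
        wavelength = float(fh.attrs["wavelength_nm"])
    grid = GridSpec(mu_a.shape[0], mu_a.shape[1], spacing)
    return OpticalPropertyMap(grid, wavelength, mu_a, mu_s, g), labels
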