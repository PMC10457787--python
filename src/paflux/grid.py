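"""Grid geometry and label-map containers.

Coordinate convention: row index = depth z, increasing downward from the
illuminated surface at row 0; column index = lateral x. Pixel centers sit at
(i + 0.5) * spacing. All lengths are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Tissue class labels
BACKGROUND = 0
SKIN = 1
ARTERY = 2
VEIN = 3

LABEL_NAMES = {BACKGROUND: "background", SKIN: "skin", ARTERY: "artery", VEIN: "vein"}
VESSEL_LABELS = (ARTERY, VEIN)


@dataclass(frozen=True)
class GridSpec:
    """Regular 2-D grid over (depth, lateral) with square pixels.

    Full-scale default: 128 x 256 pixels at 0.15625 mm spacing, i.e. a
    20 mm (depth) x 40 mm (lateral) field of view.
    """

    n_depth: int = 128
    n_lateral: int = 256
    spacing: float = 0.15625

    def __post_init__(self) -> None:
        if self.n_depth < 8 or self.n_lateral < 8:
            raise ValueError("grid must be at least 8 x 8 pixels")
        if not self.spacing > 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def depth_mm(self) -> float:
        return self.n_depth * self.spacing

    @property
    def lateral_mm(self) -> float:
        return self.n_lateral * self.spacing

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_depth, self.n_lateral)

    def depth_centers(self) -> np.ndarray:
        return (np.arange(self.n_depth) + 0.5) * self.spacing

    def lateral_centers(self) -> np.ndarray:
        return (np.arange(self.n_lateral) + 0.5) * self.spacing


def desk_grid() -> GridSpec:
    """Reduced 64 x 128 grid covering the same 20 x 40 mm field of view."""
    return GridSpec(n_depth=64, n_lateral=128, spacing=0.3125)


@dataclass
class Vessel:
    """Circular cross-section of a cylinder running out of plane."""

    center_depth: float  # mm
    center_lateral: float  # mm
    radius: float  # mm
    label: int  # ARTERY or VEIN
    oxygenation: float  # blood oxygen saturation in [0, 1]


@dataclass
class LabelMap:
    """Integer tissue-class map plus the vessel table that produced it.

    ``vessel_ids`` assigns 0 to non-vessel pixels and 1..n to pixels of the
    n-th vessel, so per-vessel optical properties (e.g. oxygenation) can be
    painted without overloading the class labels.
    """

    grid: GridSpec
    labels: np.ndarray  # (n_depth, n_lateral) int8
    vessels: list[Vessel] = field(default_factory=list)
    vessel_ids: np.ndarray | None = None
    skin_rows: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.labels.shape != self.grid.shape:
            raise ValueError("label array shape does not match grid")
        if self.vessel_ids is None:
            self.vessel_ids = np.zeros_like(self.labels)

    def validate(self) -> None:
        known = {BACKGROUND, SKIN, ARTERY, VEIN}
        if not set(np.unique(self.labels)).issubset(known):
            raise ValueError("unknown label value present")
        if self.skin_rows > 0:
            band = self.labels[: self.skin_rows]
            if not np.all(band == SKIN):
                raise ValueError("skin band is not contiguous from the surface")
            below = self.labels[self.skin_rows :]
            if np.any(below == SKIN):
                raise ValueError("skin pixels below the skin band")
        vessel_mask = np.isin(self.labels, VESSEL_LABELS)
        if np.any(vessel_mask[: self.skin_rows]):
            raise ValueError("vessel pixels inside the skin band")
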