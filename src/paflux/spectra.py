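"""Packaged chromophore absorption spectra.

The table covers the 700-850 nm range at 10 nm knots for deoxyhemoglobin
(``hb``), oxyhemoglobin (``hbo2``), water, fat and melanin. Hemoglobin
values are expressed per unit *whole-blood-equivalent* volume fraction
(150 g/L hemoglobin), melanin per unit melanosome fraction, water/fat per
unit pure-substance fraction; all in mm^-1. Queries between knots are
linearly interpolated; queries outside the tabulated range are rejected.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd


@lru_cache(maxsize=1)
def load_chromophore_table() -> pd.DataFrame:
    with resources.files("paflux.data").joinpath("chromophores.csv").open() as fh:
        table = pd.read_csv(fh)
    return table


@lru_cache(maxsize=32)
def _spectrum(chromophore_id: str) -> tuple[np.ndarray, np.ndarray]:
    table = load_chromophore_table()
    rows = table[table["chromophore"] == chromophore_id]
    if rows.empty:
        known = sorted(table["chromophore"].unique())
        raise KeyError(f"unknown chromophore {chromophore_id!r}; known: {known}")
    order = np.argsort(rows["wavelength_nm"].to_numpy())
    wl = rows["wavelength_nm"].to_numpy(dtype=float)[order]
    mua = rows["absorption_mm1_per_unit_fraction"].to_numpy(dtype=float)[order]
    return wl, mua


def chromophore_absorption(chromophore_id: str, wavelength: float) -> float:
    """Absorption coefficient (mm^-1) per unit volume fraction at ``wavelength`` nm."""
    wl, mua = _spectrum(chromophore_id)
    if wavelength < wl[0] or wavelength > wl[-1]:
        raise ValueError(
            f"wavelength {wavelength} nm outside tabulated range "
            f"[{wl[0]:.0f}, {wl[-1]:.0f}] for {chromophore_id!r}"
        )
    return float(np.interp(wavelength, wl, mua))


def available_chromophores() -> list[str]:
    return sorted(load_chromophore_table()["chromophore"].unique())
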