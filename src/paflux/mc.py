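"""Voxel Monte Carlo photon transport and initial-pressure synthesis.

Weighted-packet transport ("hop-drop-spin") on a regular voxel grid:
exponential step sampling against mu_t = mu_a + mu_s with per-voxel
re-evaluation of the remaining optical depth at boundary crossings,
absorbed-weight fluence estimation, Henyey-Greenstein scattering and
Russian roulette below a threshold weight. Boundaries are matched
(absorbing); refractive-index mismatch is out of scope.

The 2-D optical maps are extruded uniformly out of plane into a slab of
configurable half-thickness and transport is performed in three
dimensions; fluence is scored on a thin central out-of-plane bin. This
keeps out-of-plane photon loss — the dominant difference between 2-D and
3-D transport — while the inputs and outputs stay 2-D images.

Fluence is reported per launched photon (mm^-2); the initial pressure is
p0 = Grueneisen * mu_a * phi with the Grueneisen parameter fixed at 1, so
p0 carries arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .grid import GridSpec
from .tissue import OpticalPropertyMap

__all__ = [
    "IlluminationSpec",
    "TransportConfig",
    "FluenceMap",
    "InitialPressureMap",
    "sample_hg_cosine",
    "simulate_fluence",
    "initial_pressure",
    "mc_noise_curve",
]


@dataclass(frozen=True)
class IlluminationSpec:
    """Collimated slit at the top surface, normal incidence downward.

    ``center`` defaults to the lateral center of the grid. The default
    30 mm width mirrors a handheld photoacoustic probe's slit illumination.
    """

    width: float = 30.0  # mm
    center: float | None = None  # mm; None -> grid center

    def bounds(self, grid: GridSpec) -> tuple[float, float]:
        if not self.width > 0:
            raise ValueError("slit width must be positive")
        if self.width > grid.lateral_mm:
            raise ValueError("slit wider than the lateral grid extent")
        center = grid.lateral_mm / 2.0 if self.center is None else self.center
        lo = center - self.width / 2.0
        hi = center + self.width / 2.0
        if lo < 0.0 or hi > grid.lateral_mm:
            raise ValueError("slit does not fit inside the grid")
        return lo, hi


@dataclass(frozen=True)
class TransportConfig:
    """Photon budget, RNG seed and transport numerics.

    ``extrusion_half_mm`` sets the out-of-plane slab half-thickness;
    ``score_y_bins`` the number of central out-of-plane voxels integrated
    into the reported 2-D fluence (0 means the full slab).
    """

    n_photons: int = 1_000_000
    seed: int = 0
    extrusion_half_mm: float = 10.0
    roulette_threshold: float = 1e-4
    roulette_survive: float = 0.1
    score_y_bins: int = 1

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be at least 1")
        if not 0.0 < self.roulette_threshold < 1.0:
            raise ValueError("roulette threshold must lie in (0, 1)")
        if not 0.0 < self.roulette_survive <= 1.0:
            raise ValueError("roulette survival probability must lie in (0, 1]")
        if not self.extrusion_half_mm > 0:
            raise ValueError("extrusion half-thickness must be positive")


@dataclass
class FluenceMap:
    """Fluence per launched photon on the scored central slice (mm^-2)."""

    grid: GridSpec
    phi: np.ndarray
    n_photons: int
    seed: int
    totals: dict = field(default_factory=dict)

    def weight_balance_error(self) -> float:
        """|launched - deposited - escaped - net roulette loss| / launched."""
        t = self.totals
        balance = t["deposited"] + t["escaped"] + t["roulette_lost"] - t["roulette_gained"]
        return abs(t["launched"] - balance) / t["launched"]


@dataclass
class InitialPressureMap:
    """p0 = Grueneisen * mu_a * phi (arbitrary units, Grueneisen = 1)."""

    grid: GridSpec
    p0: np.ndarray


def sample_hg_cosine(g, u):
    """Inverse-CDF sample of the Henyey-Greenstein deflection cosine.

    For g = 0 the distribution is isotropic: cos(theta) = 2u - 1. Accepts
    scalars or arrays (broadcast).
    """
    g = np.asarray(g, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(g < 0) or np.any(g >= 1):
        raise ValueError("anisotropy g must lie in [0, 1)")
    iso = 2.0 * u - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (1.0 - g**2) / (1.0 - g + 2.0 * g * u)
        aniso = (1.0 + g**2 - frac**2) / (2.0 * g)
    out = np.where(g == 0.0, iso, aniso)
    out = np.clip(out, -1.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


@njit(cache=True, fastmath=True, inline="always")
def _rand(state):
    """xorshift64* uniform variate in [0, 1) with 53-bit resolution."""
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    state[0] = x
    return np.float64(
        (x * np.uint64(2685821657736338717)) >> np.uint64(11)
    ) * (1.0 / 9007199254740992.0)


@njit(cache=True, fastmath=True, inline="always")
def _seed_state(seed):
    """splitmix64 scramble of the user seed into a nonzero RNG state."""
    z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1E65B9F9)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z ^= z >> np.uint64(31)
    if z == np.uint64(0):
        z = np.uint64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True, fastmath=True)
def _hg_cosine_scalar(g, u):
    if g == 0.0:
        return 2.0 * u - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - frac * frac) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, fastmath=True)
def _transport_kernel(mua, mus, gmap, spacing, ny, y0, y1,
                      slit_lo, slit_hi, n_photons, seed,
                      w_thresh, p_surv):
    """Single-threaded weighted-packet transport; returns the central-slice
    deposit map and the weight-accounting totals.

    Voxel traversal is DDA-style: the current voxel index triple is explicit
    state and is stepped by +/-1 along the binding axis at each boundary
    crossing, so grazing-incidence photons cannot stall on a boundary.
    """
    state = np.empty(1, dtype=np.uint64)
    state[0] = _seed_state(seed)
    nz, nx = mua.shape

    dep2d = np.zeros((nz, nx))
    deposited = 0.0
    escaped = 0.0
    roulette_lost = 0.0
    roulette_gained = 0.0

    for _ in range(n_photons):
        x = slit_lo + (slit_hi - slit_lo) * _rand(state)
        y = ny * spacing * _rand(state)
        z = 0.0
        dx = 0.0
        dy = 0.0
        dz = 1.0
        w = 1.0
        iz = 0
        ix = int(x / spacing)
        if ix >= nx:
            ix = nx - 1
        iy = int(y / spacing)
        if iy >= ny:
            iy = ny - 1
        s = -np.log(1.0 - _rand(state))  # optical depth to interaction
        while True:
            if iz < 0 or iz >= nz or ix < 0 or ix >= nx or iy < 0 or iy >= ny:
                escaped += w
                break
            ma = mua[iz, ix]
            ms = mus[iz, ix]
            mt = ma + ms
            # distance to the voxel boundary along the current direction and
            # the axis (0=z, 1=x, 2=y) on which it is reached
            tb = 1e30
            axis = -1
            if dz > 0.0:
                t = ((iz + 1) * spacing - z) / dz
                if t < tb:
                    tb = t
                    axis = 0
            elif dz < 0.0:
                t = (iz * spacing - z) / dz
                if t < tb:
                    tb = t
                    axis = 0
            if dx > 0.0:
                t = ((ix + 1) * spacing - x) / dx
                if t < tb:
                    tb = t
                    axis = 1
            elif dx < 0.0:
                t = (ix * spacing - x) / dx
                if t < tb:
                    tb = t
                    axis = 1
            if dy > 0.0:
                t = ((iy + 1) * spacing - y) / dy
                if t < tb:
                    tb = t
                    axis = 2
            elif dy < 0.0:
                t = (iy * spacing - y) / dy
                if t < tb:
                    tb = t
                    axis = 2
            if tb < 0.0:
                tb = 0.0

            d_int = s / mt if mt > 1e-12 else 1e30
            if d_int <= tb:
                # interaction inside this voxel
                z += dz * d_int
                x += dx * d_int
                y += dy * d_int
                dep = w * ma / mt
                deposited += dep
                if y0 <= iy < y1:
                    dep2d[iz, ix] += dep
                w -= dep
                if w < w_thresh:
                    if _rand(state) < p_surv:
                        roulette_gained += w * (1.0 / p_surv - 1.0)
                        w /= p_surv
                    else:
                        roulette_lost += w
                        break
                # spin: Henyey-Greenstein deflection, uniform azimuth
                cost = _hg_cosine_scalar(gmap[iz, ix], _rand(state))
                sint = np.sqrt(1.0 - cost * cost)
                phi_ang = 2.0 * np.pi * _rand(state)
                cosp = np.cos(phi_ang)
                sinp = np.sin(phi_ang)
                if abs(dz) > 0.99999:
                    dx = sint * cosp
                    dy = sint * sinp
                    dz = cost * (1.0 if dz >= 0.0 else -1.0)
                else:
                    denom = np.sqrt(1.0 - dz * dz)
                    dx_new = sint * (dx * dz * cosp - dy * sinp) / denom + dx * cost
                    dy_new = sint * (dy * dz * cosp + dx * sinp) / denom + dy * cost
                    dz_new = -sint * cosp * denom + dz * cost
                    dx = dx_new
                    dy = dy_new
                    dz = dz_new
                norm = np.sqrt(dx * dx + dy * dy + dz * dz)
                dx /= norm
                dy /= norm
                dz /= norm
                s = -np.log(1.0 - _rand(state))
            else:
                # advance to the boundary and step the binding voxel index
                z += dz * tb
                x += dx * tb
                y += dy * tb
                if mt > 1e-12:
                    s -= tb * mt
                    if s < 0.0:
                        s = 0.0
                if axis == 0:
                    if dz > 0.0:
                        iz += 1
                        z = iz * spacing
                    else:
                        z = iz * spacing
                        iz -= 1
                elif axis == 1:
                    if dx > 0.0:
                        ix += 1
                        x = ix * spacing
                    else:
                        x = ix * spacing
                        ix -= 1
                else:
                    if dy > 0.0:
                        iy += 1
                        y = iy * spacing
                    else:
                        y = iy * spacing
                        iy -= 1

    return dep2d, deposited, escaped, roulette_lost, roulette_gained


def simulate_fluence(opt: OpticalPropertyMap, illum: IlluminationSpec,
                     cfg: TransportConfig) -> FluenceMap:
    """Run the transport and return fluence per launched photon.

    Identical (map, illumination, config) including the seed reproduce the
    fluence bitwise on one build. Raises if the medium has zero mu_t
    everywhere (no interaction could ever be scored).
    """
    opt.validate()
    mu_t = opt.mu_a + opt.mu_s
    if not np.any(mu_t > 0):
        raise ValueError("degenerate medium: mu_t is zero everywhere")
    slit_lo, slit_hi = illum.bounds(opt.grid)
    spacing = opt.grid.spacing
    ny = max(1, int(round(2.0 * cfg.extrusion_half_mm / spacing)))
    if cfg.score_y_bins <= 0 or cfg.score_y_bins >= ny:
        y0, y1 = 0, ny
    else:
        y0 = (ny - cfg.score_y_bins) // 2
        y1 = y0 + cfg.score_y_bins
    dep2d, deposited, escaped, r_lost, r_gained = _transport_kernel(
        np.ascontiguousarray(opt.mu_a, dtype=np.float64),
        np.ascontiguousarray(opt.mu_s, dtype=np.float64),
        np.ascontiguousarray(opt.g, dtype=np.float64),
        spacing, ny, y0, y1, slit_lo, slit_hi,
        cfg.n_photons, cfg.seed,
        cfg.roulette_threshold, cfg.roulette_survive,
    )
    score_volume = spacing**3 * (y1 - y0)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = dep2d / (opt.mu_a * score_volume * cfg.n_photons)
    phi[~np.isfinite(phi)] = 0.0
    return FluenceMap(
        grid=opt.grid,
        phi=phi,
        n_photons=cfg.n_photons,
        seed=cfg.seed,
        totals={
            "launched": float(cfg.n_photons),
            "deposited": deposited,
            "escaped": escaped,
            "roulette_lost": r_lost,
            "roulette_gained": r_gained,
        },
    )


def initial_pressure(opt: OpticalPropertyMap, phi: FluenceMap,
                     grueneisen: float = 1.0) -> InitialPressureMap:
    """p0 = Grueneisen * mu_a * phi, pixelwise."""
    if opt.grid != phi.grid:
        raise ValueError("optical map and fluence map grids do not match")
    return InitialPressureMap(grid=opt.grid, p0=grueneisen * opt.mu_a * phi.phi)


def simulate_p0(opt: OpticalPropertyMap, illum: IlluminationSpec,
                cfg: TransportConfig, grueneisen: float = 1.0) -> InitialPressureMap:
    """Convenience: transport then fluence-to-pressure conversion."""
    return initial_pressure(opt, simulate_fluence(opt, illum, cfg), grueneisen)


def mc_noise_curve(opt: OpticalPropertyMap, photon_counts: list[int],
                   reference_count: int, seed: int,
                   illum: IlluminationSpec | None = None,
                   cfg: TransportConfig | None = None) -> list[tuple[int, float]]:
    """Max-normalized MAE of reduced-photon runs against a reference run.

    Each entry pairs a photon count with the mean absolute difference of
    its p0 map to the reference p0 map, both divided by the reference
    maximum. The expected trend is a 1/sqrt(N) decay.
    """
    if not photon_counts:
        raise ValueError("photon_counts must be nonempty")
    if any(n > reference_count for n in photon_counts):
        raise ValueError("all photon counts must be <= the reference count")
    illum = illum or IlluminationSpec()
    cfg = cfg or TransportConfig()
    from dataclasses import replace

    ref_cfg = replace(cfg, n_photons=reference_count, seed=seed)
    ref = simulate_p0(opt, illum, ref_cfg).p0
    ref_max = ref.max()
    if ref_max <= 0:
        raise ValueError("reference p0 is identically zero")
    curve = []
    for k, count in enumerate(photon_counts):
        run_seed = seed if count == reference_count else seed + k + 1
        run_cfg = replace(cfg, n_photons=count, seed=run_seed)
        p0 = simulate_p0(opt, illum, run_cfg).p0
        mae = float(np.mean(np.abs(p0 - ref)) / ref_max)
        curve.append((count, mae))
    return curve
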