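"""Dataset generation and the HDF5 dataset container.

Layout (one file per dataset):

    /samples/<id>/labels                  int8 tissue classes
    /samples/<id>/wavelength_<nm>/mua     mm^-1
    /samples/<id>/wavelength_<nm>/mus     mm^-1
    /samples/<id>/wavelength_<nm>/g       dimensionless
    /samples/<id>/wavelength_<nm>/p0      arbitrary units
    /splits/{train,val,test}              sample indices

Global attributes record the grid, photon count, wavelengths and the
master seed. p0 is stored in units of the *illuminated-area-scaled*
fluence (incident fluence ~ 1 at the surface), which gives the
log-compression a meaningful dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .config import PipelineConfig, RunManifest
from .grid import GridSpec, LabelMap
from .mc import simulate_fluence, initial_pressure
from .nn.transforms import log_compress
from .tissue import (adjust_scattering_for_fixed_g, assign_optical_properties,
                     sample_forearm_geometry, sample_tissue_library,
                     OpticalPropertyMap)

__all__ = ["DatasetSplit", "generate_dataset", "stratified_split",
           "PADataset", "generate_sample_maps"]


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/validation/test sample indices."""

    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]

    def __post_init__(self) -> None:
        pools = [set(self.train), set(self.val), set(self.test)]
        total = sum(len(p) for p in pools)
        if len(set().union(*pools)) != total:
            raise ValueError("split index lists overlap")

    @property
    def n_samples(self) -> int:
        return len(self.train) + len(self.val) + len(self.test)

    def n_pairs(self, n_wavelengths: int) -> dict[str, int]:
        """Image-pair bookkeeping, e.g. training+validation pair count."""
        return {
            "train": len(self.train) * n_wavelengths,
            "val": len(self.val) * n_wavelengths,
            "test": len(self.test) * n_wavelengths,
            "train_val": (len(self.train) + len(self.val)) * n_wavelengths,
        }


def stratified_split(strata: np.ndarray, fractions: tuple[float, float, float],
                     seed: int) -> DatasetSplit:
    """Split stratified on an integer covariate (here: vessel count).

    Global bucket sizes are exact (val and test rounded from the
    fractions, train takes the rest — e.g. 1100 samples at 0.7/0.1/0.2
    give exactly 770/110/220). Within each stratum, shuffled indices are
    dealt to buckets following the global proportions; remainders are
    balanced across strata so the global counts hold exactly.
    """
    strata = np.asarray(strata)
    n = len(strata)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("invalid split fractions")
    rng = np.random.default_rng(seed)
    quota = {"train": n_train, "val": n_val, "test": n_test}
    buckets: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    leftovers: list[int] = []
    for value in np.unique(strata):
        idx = rng.permutation(np.flatnonzero(strata == value))
        k = len(idx)
        take = {
            "val": int(np.floor(fractions[1] * k)),
            "test": int(np.floor(fractions[2] * k)),
        }
        take["train"] = int(np.floor(fractions[0] * k))
        pos = 0
        for name in ("val", "test", "train"):
            grab = min(take[name], quota[name] - len(buckets[name]))
            buckets[name].extend(idx[pos:pos + grab].tolist())
            pos += grab
        leftovers.extend(idx[pos:].tolist())
    leftovers = rng.permutation(np.array(leftovers, dtype=int)).tolist()
    for idx in leftovers:
        deficits = {k: quota[k] - len(buckets[k]) for k in buckets}
        bucket = max(deficits, key=lambda k: (deficits[k], k))
        buckets[bucket].append(idx)
    # strata flooring can overfill no bucket beyond quota only via leftovers,
    # which the deficit rule prevents; assert the exact global counts
    for name, target in quota.items():
        if len(buckets[name]) != target:
            raise AssertionError("stratified split failed to meet exact counts")
    return DatasetSplit(tuple(sorted(buckets["train"])),
                        tuple(sorted(buckets["val"])),
                        tuple(sorted(buckets["test"])))


def generate_sample_maps(config: PipelineConfig, index: int
                         ) -> tuple[LabelMap, dict[float, OpticalPropertyMap]]:
    """Geometry plus per-wavelength optical maps for one sample."""
    geom_cfg = replace(config.geometry, seed=config.stage_seed("geometry", index))
    label_map = sample_forearm_geometry(geom_cfg, config.grid)
    lib_rng = np.random.default_rng(config.stage_seed("library", index))
    library = sample_tissue_library(geom_cfg, lib_rng)
    maps = {}
    for wavelength in config.wavelengths:
        opt = assign_optical_properties(label_map, wavelength, library)
        if config.fixed_g is not None:
            opt = adjust_scattering_for_fixed_g(opt, config.fixed_g)
        maps[wavelength] = opt
    return label_map, maps


def _fluence_scale(config: PipelineConfig) -> float:
    if config.fluence_scale is not None:
        return config.fluence_scale
    spacing = config.grid.spacing
    ny = max(1, int(round(2.0 * config.transport.extrusion_half_mm / spacing)))
    return config.illumination.width * ny * spacing  # illuminated area, mm^2


def generate_dataset(config: PipelineConfig, out_path,
                     progress: bool = False) -> RunManifest:
    """Generate geometries, optical maps and Monte Carlo p0 targets.

    Deterministic in the master seed: geometry, tissue library and
    transport seeds are all derived per (stage, sample). The split is
    stratified on vessel count.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(),
                           master_seed=config.master_seed, version=__version__)
    scale = _fluence_scale(config)
    vessel_counts = np.zeros(config.n_samples, dtype=int)
    with h5py.File(out_path, "w") as fh:
        fh.attrs["spacing_mm"] = config.grid.spacing
        fh.attrs["n_depth"] = config.grid.n_depth
        fh.attrs["n_lateral"] = config.grid.n_lateral
        fh.attrs["n_photons"] = config.transport.n_photons
        fh.attrs["wavelengths_nm"] = list(config.wavelengths)
        fh.attrs["master_seed"] = config.master_seed
        fh.attrs["fluence_scale"] = scale
        fh.attrs["slit_width_mm"] = config.illumination.width
        fh.attrs["extrusion_half_mm"] = config.transport.extrusion_half_mm
        fh.attrs["score_y_bins"] = config.transport.score_y_bins
        samples = fh.create_group("samples")
        for i in range(config.n_samples):
            label_map, maps = generate_sample_maps(config, i)
            vessel_counts[i] = len(label_map.vessels)
            grp = samples.create_group(f"s{i:04d}")
            grp.create_dataset("labels", data=label_map.labels)
            grp.attrs["geometry_seed"] = label_map.seed
            for wavelength, opt in maps.items():
                mc_seed = config.stage_seed(f"mc_{wavelength:.0f}", i)
                cfg = replace(config.transport, seed=mc_seed)
                phi = simulate_fluence(opt, config.illumination, cfg)
                p0 = initial_pressure(opt, phi).p0 * scale
                sub = grp.create_group(f"wavelength_{wavelength:.0f}")
                sub.create_dataset("mua", data=opt.mu_a.astype(np.float32))
                sub.create_dataset("mus", data=opt.mu_s.astype(np.float32))
                sub.create_dataset("g", data=opt.g.astype(np.float32))
                sub.create_dataset("p0", data=p0.astype(np.float32))
                sub.attrs["seed"] = mc_seed
                manifest.stage_seeds[f"mc_{wavelength:.0f}_{i}"] = mc_seed
            if progress:
                print(f"sample {i + 1}/{config.n_samples}", flush=True)
        split = stratified_split(vessel_counts, config.split_fractions,
                                 config.stage_seed("split"))
        splits = fh.create_group("splits")
        splits.create_dataset("train", data=np.array(split.train, dtype=int))
        splits.create_dataset("val", data=np.array(split.val, dtype=int))
        splits.create_dataset("test", data=np.array(split.test, dtype=int))
    manifest.record_output(out_path)
    return manifest


class PADataset:
    """In-memory view of a dataset file, organised as (sample, wavelength)
    image pairs: 3-channel optical input, linear p0 reference and its
    log-compressed training target."""

    def __init__(self, path):
        self.path = Path(path)
        with h5py.File(self.path, "r") as fh:
            self.spacing = float(fh.attrs["spacing_mm"])
            self.n_photons = int(fh.attrs["n_photons"])
            self.wavelengths = [float(w) for w in fh.attrs["wavelengths_nm"]]
            self.fluence_scale = float(fh.attrs.get("fluence_scale", 1.0))
            self.slit_width_mm = float(fh.attrs.get("slit_width_mm", 30.0))
            self.extrusion_half_mm = float(fh.attrs.get("extrusion_half_mm", 10.0))
            self.score_y_bins = int(fh.attrs.get("score_y_bins", 1))
            self.master_seed = int(fh.attrs["master_seed"])
            sample_names = sorted(fh["samples"].keys())
            self.sample_ids = sample_names
            self.labels = np.stack(
                [fh[f"samples/{s}/labels"][()] for s in sample_names]
            )
            inputs, targets = [], []
            self.pair_index: list[tuple[int, float]] = []
            for si, s in enumerate(sample_names):
                for w in self.wavelengths:
                    sub = fh[f"samples/{s}/wavelength_{w:.0f}"]
                    inputs.append(np.stack([sub["mua"][()], sub["mus"][()],
                                            sub["g"][()]]))
                    targets.append(sub["p0"][()])
                    self.pair_index.append((si, w))
            self.inputs = np.stack(inputs).astype(np.float32)
            self.p0 = np.stack(targets).astype(np.float32)
            self.split = DatasetSplit(
                tuple(int(i) for i in fh["splits/train"][()]),
                tuple(int(i) for i in fh["splits/val"][()]),
                tuple(int(i) for i in fh["splits/test"][()]),
            )
        self.targets = log_compress(self.p0)[:, None, :, :].astype(np.float32)
        self.grid = GridSpec(self.inputs.shape[2], self.inputs.shape[3],
                             self.spacing)

    def pair_rows(self, sample_indices) -> np.ndarray:
        """Row indices of all (sample, wavelength) pairs for given samples."""
        wanted = set(int(s) for s in sample_indices)
        return np.array(
            [k for k, (si, _) in enumerate(self.pair_index) if si in wanted],
            dtype=int,
        )

    def export_npz(self, path) -> None:
        np.savez_compressed(
            path, inputs=self.inputs, p0=self.p0, labels=self.labels,
            train=np.array(self.split.train), val=np.array(self.split.val),
            test=np.array(self.split.test),
            wavelengths=np.array(self.wavelengths), spacing=self.spacing,
        )
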