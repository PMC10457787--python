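"""Shared fixtures.

Two dataset tiers: a seconds-scale miniature dataset for functional tests,
and the desk-scale study fixture (100 samples, 64 x 128 grid, 10^6 photons
per map) with trained surrogates, shared by the training-level tests. Both
are generated on the fly; nothing is read from disk fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from paflux.config import PipelineConfig
from paflux.dataset import PADataset, generate_dataset
from paflux.grid import GridSpec
from paflux.mc import IlluminationSpec, TransportConfig
from paflux.nn import build_model
from paflux.tissue import GeometryConfig
from paflux.training import TrainConfig, train_surrogate


def fd_gradient_error(f, x, analytic_grad, n_probes: int = 8,
                      eps: float = 1e-6, seed: int = 0) -> float:
    """Max relative central-difference error over random probe entries."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_probes):
        idx = tuple(rng.integers(0, s) for s in x.shape)
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        numeric = (f(xp) - f(xm)) / (2.0 * eps)
        denom = max(abs(numeric), abs(analytic_grad[idx]), 1e-8)
        worst = max(worst, abs(numeric - analytic_grad[idx]) / denom)
    return worst


@pytest.fixture(scope="session")
def tiny_config() -> PipelineConfig:
    return PipelineConfig(
        grid=GridSpec(16, 32, 1.25),
        geometry=GeometryConfig(vessel_count=(1, 3),
                                vessel_radius_mm=(1.0, 2.5),
                                vessel_depth_mm=(4.0, 15.0)),
        illumination=IlluminationSpec(width=30.0),
        transport=TransportConfig(n_photons=20_000, extrusion_half_mm=5.0),
        wavelengths=(700.0, 850.0),
        n_samples=8,
        split_fractions=(0.5, 0.25, 0.25),
        master_seed=3,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config, tmp_path_factory) -> PADataset:
    path = tmp_path_factory.mktemp("data") / "tiny.h5"
    generate_dataset(tiny_config, path)
    return PADataset(path)


@pytest.fixture(scope="session")
def desk_fixture(tmp_path_factory) -> PADataset:
    """The desk-scale study fixture: 100 samples on the 64 x 128 grid with
    10^6-photon Monte Carlo references at 800 nm."""
    config = PipelineConfig(wavelengths=(800.0,), n_samples=100, master_seed=1)
    path = tmp_path_factory.mktemp("data") / "desk100.h5"
    generate_dataset(config, path)
    return PADataset(path)


@pytest.fixture(scope="session")
def fno_train_config() -> TrainConfig:
    return TrainConfig(epochs=12, batch_size=8, loss="rel_l2", seed=0)


@pytest.fixture(scope="session")
def trained_fno(desk_fixture, fno_train_config):
    ds = desk_fixture
    tr = ds.pair_rows(ds.split.train)
    va = ds.pair_rows(ds.split.val)
    model = build_model("fno", {"seed": 0})
    model, history = train_surrogate(
        model, ds.inputs[tr], ds.targets[tr], ds.inputs[va], ds.targets[va],
        fno_train_config,
    )
    return model, history


@pytest.fixture(scope="session")
def trained_unet(desk_fixture):
    ds = desk_fixture
    tr = ds.pair_rows(ds.split.train)
    va = ds.pair_rows(ds.split.val)
    model = build_model("unet", {"seed": 0})
    model, history = train_surrogate(
        model, ds.inputs[tr], ds.targets[tr], ds.inputs[va], ds.targets[va],
        TrainConfig(epochs=8, batch_size=8, loss="mse", seed=0),
    )
    return model, history
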