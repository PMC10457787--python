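"""Supervised training of the surrogates and the evaluation experiments.

The optimization recipe: Adam with initial learning rate 0.01 and weight
decay 1e-4, batch size 16, up to 200 epochs, reduce-on-plateau scheduling
(factor 0.5, patience 5, relative threshold 1e-4), joint left-right flip
augmentation with probability 0.5, model selection at the epoch of minimal
validation loss. The U-Net trains with mean squared error, the FNO with
the relative L2 loss; both losses act on the log-compressed pressure.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import PADataset

from .mc import IlluminationSpec, TransportConfig, simulate_fluence, initial_pressure
from .metrics import (error_map, max_normalized_mae, psnr, ssim)
from .nn.autodiff import Tensor
from .nn.modules import Module
from .nn.optim import Adam, ReduceLROnPlateau
from .nn.transforms import log_expand
from .tissue import OpticalPropertyMap

__all__ = [
    "TrainConfig", "relative_l2_loss", "train_surrogate", "predict",
    "evaluate_model", "photon_equivalence_experiment",
    "training_size_ablation", "boundary_error_experiment",
    "aggregate_by_wavelength",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 0.01
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    scheduler_threshold: float = 1e-4
    weight_decay: float = 1e-4
    loss: str = "mse"  # "mse" (U-Net) or "rel_l2" (FNO)
    flip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be at least 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.loss not in ("mse", "rel_l2"):
            raise ValueError("loss must be 'mse' or 'rel_l2'")


def relative_l2_loss(estimate, reference) -> float:
    """Batch-averaged per-sample ||est - ref|| / ||ref|| (numpy arrays).

    Accepts (N, ...) stacks; a single pair may be passed with N = 1.
    """
    est = np.asarray(estimate, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("shapes differ")
    axes = tuple(range(1, est.ndim))
    denom = np.sqrt((ref**2).sum(axis=axes))
    if np.any(denom == 0):
        raise ValueError("reference with zero norm in batch")
    num = np.sqrt(((est - ref) ** 2).sum(axis=axes))
    return float((num / denom).mean())


def _tensor_loss(pred: Tensor, target: np.ndarray, kind: str) -> Tensor:
    if kind == "mse":
        return ((pred - Tensor(target)) ** 2).mean()
    axes = (1, 2, 3)
    denom = np.sqrt((target.astype(np.float64) ** 2).sum(axis=axes))
    if np.any(denom == 0):
        raise ValueError("reference with zero norm in batch")
    diff = pred - Tensor(target)
    num = ((diff**2).sum(axis=axes) + 1e-20) ** 0.5
    return (num * Tensor(1.0 / denom)).mean()


def _numpy_loss(pred: np.ndarray, target: np.ndarray, kind: str) -> float:
    if kind == "mse":
        return float(np.mean((pred - target) ** 2))
    return relative_l2_loss(pred, target)


def predict(model: Module, inputs: np.ndarray, batch_size: int = 8
            ) -> np.ndarray:
    """Evaluation-mode forward pass over an (N, 3, H, W) stack; returns the
    (N, H, W) log-compressed pressure estimates."""
    model.eval()
    outs = []
    for lo in range(0, len(inputs), batch_size):
        chunk = inputs[lo:lo + batch_size]
        outs.append(model(Tensor(chunk)).data[:, 0])
    return np.concatenate(outs, axis=0)


def train_surrogate(model: Module, train_inputs: np.ndarray,
                    train_targets: np.ndarray, val_inputs: np.ndarray,
                    val_targets: np.ndarray, config: TrainConfig
                    ) -> tuple[Module, pd.DataFrame]:
    """Train with the standard recipe; returns the model restored to its
    best-validation epoch plus the per-epoch history.

    History row 0 records the untrained validation loss; the scheduler
    monitors the validation loss from epoch 1 on. Raises on non-finite
    training loss (divergence guard).
    """
    if len(train_inputs) == 0 or len(val_inputs) == 0:
        raise ValueError("train and validation splits must be nonempty")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate,
                     weight_decay=config.weight_decay)
    scheduler = ReduceLROnPlateau(
        optimizer, factor=config.scheduler_factor,
        patience=config.scheduler_patience,
        threshold=config.scheduler_threshold,
    )
    history = []
    val0 = _numpy_loss(predict(model, val_inputs)[:, None], val_targets,
                       config.loss)
    history.append({"epoch": 0, "train_loss": np.nan, "val_loss": val0,
                    "learning_rate": optimizer.lr})
    best_val = val0
    best_state = copy.deepcopy(model.state_dict())
    best_epoch = 0

    n = len(train_inputs)
    for epoch in range(1, config.epochs + 1):
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb = train_inputs[idx].copy()
            yb = train_targets[idx].copy()
            flip = rng.random(len(idx)) < config.flip_prob
            xb[flip] = xb[flip, :, :, ::-1]
            yb[flip] = yb[flip, :, :, ::-1]
            optimizer.zero_grad()
            loss = _tensor_loss(model(Tensor(np.ascontiguousarray(xb))),
                                np.ascontiguousarray(yb), config.loss)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training loss diverged (non-finite) at epoch {epoch}"
                )
            loss.backward()
            optimizer.step()
            epoch_loss += value
            n_batches += 1
        val_loss = _numpy_loss(predict(model, val_inputs)[:, None],
                               val_targets, config.loss)
        scheduler.step(val_loss)
        history.append({"epoch": epoch, "train_loss": epoch_loss / n_batches,
                        "val_loss": val_loss, "learning_rate": optimizer.lr})
        if val_loss < best_val:
            best_val = val_loss
            best_state = copy.deepcopy(model.state_dict())
            best_epoch = epoch
    model.load_state_dict(best_state)
    model.eval()
    frame = pd.DataFrame(history)
    frame.attrs["best_epoch"] = best_epoch
    frame.attrs["best_val_loss"] = best_val
    return model, frame


def evaluate_model(model: Module | None, dataset: PADataset,
                   sample_indices=None, model_tag: str = "model",
                   log_domain: bool = False,
                   estimates: np.ndarray | None = None) -> pd.DataFrame:
    """Per-(sample, wavelength) metric records on max-normalized pressure.

    ``estimates`` may be supplied directly (e.g. reference-as-estimate
    oracle checks or reduced-photon Monte Carlo maps); otherwise the model
    is run on the dataset inputs. Metrics are computed on linear pressure
    by default; ``log_domain`` recomputes them on the log-compressed maps.
    """
    if sample_indices is None:
        sample_indices = dataset.split.test
    rows = dataset.pair_rows(sample_indices)
    if len(rows) == 0:
        raise ValueError("empty evaluation subset")
    if estimates is None:
        if model is None:
            raise ValueError("either a model or explicit estimates required")
        est_lin = log_expand(predict(model, dataset.inputs[rows]))
    else:
        est_lin = np.asarray(estimates)
    records = []
    for k, row in enumerate(rows):
        si, wavelength = dataset.pair_index[row]
        ref = dataset.p0[row]
        est = est_lin[k]
        if log_domain:
            est = np.log10(1.0 + np.clip(est, 0.0, None))
            ref = np.log10(1.0 + ref)
        records.append({
            "sample_id": dataset.sample_ids[si],
            "wavelength_nm": wavelength,
            "model": model_tag,
            "mae": max_normalized_mae(est, ref),
            "ssim": ssim(est, ref),
            "psnr_db": psnr(est, ref),
            "ref_photons": dataset.n_photons,
        })
    return pd.DataFrame(records)


def aggregate_by_wavelength(records: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles per wavelength (infinite PSNR excluded)."""
    clean = records.replace(np.inf, np.nan)
    return clean.groupby("wavelength_nm")[["mae", "ssim", "psnr_db"]].describe(
        percentiles=[0.25, 0.5, 0.75]
    )


def _optical_map_from_row(dataset: PADataset, row: int) -> OpticalPropertyMap:
    mua, mus, g = dataset.inputs[row].astype(np.float64)
    return OpticalPropertyMap(dataset.grid, dataset.pair_index[row][1],
                              mua, mus, g)


def _mc_estimate(dataset: PADataset, row: int, n_photons: int, seed: int
                 ) -> np.ndarray:
    opt = _optical_map_from_row(dataset, row)
    illum = IlluminationSpec(width=dataset.slit_width_mm)
    cfg = TransportConfig(
        n_photons=n_photons, seed=seed,
        extrusion_half_mm=dataset.extrusion_half_mm,
        score_y_bins=dataset.score_y_bins,
    )
    phi = simulate_fluence(opt, illum, cfg)
    return initial_pressure(opt, phi).p0 * dataset.fluence_scale


def photon_equivalence_experiment(model: Module, dataset: PADataset,
                                  photon_counts: list[int], seed: int = 0,
                                  sample_indices=None,
                                  model_tag: str = "fno") -> pd.DataFrame:
    """Surrogate error versus reduced-photon Monte Carlo error.

    For each test pair, the reference is the stored full-budget p0 map;
    the surrogate and fresh Monte Carlo runs at each reduced photon count
    are compared to it with the max-normalized MAE. The result table
    carries one row per (source, pair); ``attrs['equivalent_count']``
    holds the photon count whose median MAE is closest to the surrogate's.
    """
    if sample_indices is None:
        sample_indices = dataset.split.test
    rows = dataset.pair_rows(sample_indices)
    if len(rows) == 0:
        raise ValueError("empty evaluation subset")
    if any(c > dataset.n_photons for c in photon_counts):
        raise ValueError("photon counts must not exceed the reference count")
    out = []
    est_lin = log_expand(predict(model, dataset.inputs[rows]))
    for k, row in enumerate(rows):
        out.append({"source": model_tag, "row": int(row),
                    "mae": max_normalized_mae(est_lin[k], dataset.p0[row])})
    for count in photon_counts:
        for k, row in enumerate(rows):
            est = _mc_estimate(dataset, row, count,
                               seed=seed + 7919 * count + k)
            out.append({"source": f"mc@{count}", "row": int(row),
                        "mae": max_normalized_mae(est, dataset.p0[row])})
    frame = pd.DataFrame(out)
    medians = frame.groupby("source")["mae"].median()
    surrogate_median = medians[model_tag]
    mc_medians = {
        int(s.split("@")[1]): m for s, m in medians.items() if s.startswith("mc@")
    }
    frame.attrs["surrogate_median_mae"] = float(surrogate_median)
    frame.attrs["mc_median_mae"] = {k: float(v) for k, v in mc_medians.items()}
    frame.attrs["equivalent_count"] = min(
        mc_medians, key=lambda c: abs(mc_medians[c] - surrogate_median)
    )
    return frame


def training_size_ablation(model_factory, dataset: PADataset,
                           config: TrainConfig,
                           fractions=(0.25, 0.5, 0.75, 1.0)) -> pd.DataFrame:
    """Test MAE as a function of the training-set fraction.

    Subsets are nested (a smaller fraction is a prefix of a fixed seeded
    permutation of the training samples), so curves differ only in data
    volume. ``model_factory()`` must return a freshly initialised model.
    """
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(np.array(dataset.split.train))
    val_rows = dataset.pair_rows(dataset.split.val)
    results = []
    for fraction in fractions:
        n_take = max(1, int(round(fraction * len(order))))
        subset = order[:n_take]
        train_rows = dataset.pair_rows(subset)
        model = model_factory()
        model, _ = train_surrogate(
            model, dataset.inputs[train_rows], dataset.targets[train_rows],
            dataset.inputs[val_rows], dataset.targets[val_rows], config,
        )
        records = evaluate_model(model, dataset)
        results.append({"fraction": fraction, "n_train_samples": int(n_take),
                        "test_mae_median": float(records["mae"].median()),
                        "test_mae_mean": float(records["mae"].mean())})
    return pd.DataFrame(results)


def boundary_error_experiment(model: Module, dataset: PADataset,
                              low_count: int, seed: int = 0,
                              sample_indices=None) -> pd.DataFrame:
    """Error-character comparison: boundary concentration of surrogate
    error versus low-photon Monte Carlo noise on the same samples."""
    if sample_indices is None:
        sample_indices = dataset.split.test
    rows = dataset.pair_rows(sample_indices)
    est_lin = log_expand(predict(model, dataset.inputs[rows]))
    out = []
    for k, row in enumerate(rows):
        si, wavelength = dataset.pair_index[row]
        labels = dataset.labels[si]
        ref = dataset.p0[row]
        _, s_sur = error_map(est_lin[k], ref, labels=labels)
        mc_est = _mc_estimate(dataset, row, low_count, seed=seed + 31 * k)
        _, s_mc = error_map(mc_est, ref, labels=labels)
        out.append({
            "sample_id": dataset.sample_ids[si],
            "wavelength_nm": wavelength,
            "surrogate_concentration": s_sur["boundary_error_concentration"],
            "mc_concentration": s_mc["boundary_error_concentration"],
            "band_area_fraction": s_sur["band_area_fraction"],
        })
    return pd.DataFrame(out)
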