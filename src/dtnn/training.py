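"""Mini-batch SGD training with momentum and checkpoint-best early stopping.

The protocol mirrors the classic recipe for this architecture family:
minimize the squared error of molecular energies with constant-rate
stochastic gradient descent (momentum 0.9) for a fixed number of epochs,
evaluating a held-out validation MAE every epoch and returning the
parameters from the epoch with the lowest validation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import PaddedBatch, forward_batch, loss_and_grads, make_batch, zero_grads
from .data import MolecularDataset
from .featurize import GaussianGrid
from .network import EnergyScaler, ModelParams, init_params

__all__ = [
    "BOLTZMANN_KCAL",
    "ModelConfig",
    "TrainConfig",
    "TrainHistory",
    "fit_energy_stats",
    "fit",
    "evaluate_mae",
    "predict_dataset",
    "thermal_energy",
]

# Boltzmann constant in kcal mol^-1 K^-1
BOLTZMANN_KCAL = 1.987204e-3


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters and the distance grid."""

    B: int = 30               # embedding width (coefficients per atom)
    F: int = 60               # factors in the low-rank tensor layer
    H: int = 15               # hidden units in the energy head
    T: int = 2                # interaction passes
    cutoff: float | None = None
    tied: bool = True
    act: str = "tanh"
    grid: GaussianGrid = field(default_factory=GaussianGrid)
    embedding_sd: float | None = None


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Batch size and learning rate are documented package defaults, not
    claims about any published setup.
    """

    learning_rate: float = 1e-3
    momentum: float = 0.9
    epochs: int = 3000
    batch_size: int = 32
    seed: int = 0
    patience: int | None = None
    val_mae_target: float | None = None  # halt as soon as best val MAE < target
    restore_best: bool = True  # False returns final-epoch parameters instead

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch training record."""

    train_loss: list[float] = field(default_factory=list)  # standardized MSE
    val_mae: list[float] = field(default_factory=list)     # kcal/mol
    best_epoch: int = -1
    best_val_mae: float = np.inf
    epochs_run: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "val_mae": self.val_mae,
            }
        )


def fit_energy_stats(train_split: MolecularDataset, *, floor: float = 1e-8) -> EnergyScaler:
    """Mean and population s.d. of energy per atom over the training set.

    The s.d. is floored so a constant-energy (or single-molecule) training
    set still yields a usable scaler.
    """
    if len(train_split) == 0:
        raise ValueError("cannot fit energy statistics on an empty split")
    per_atom = train_split.energies() / np.array([m.n_atoms for m in train_split])
    mu = float(np.mean(per_atom))
    sigma = float(np.std(per_atom))  # population s.d.
    return EnergyScaler(E_mu=mu, E_sigma=max(sigma, floor))


def _sgd_step(params: ModelParams, grads: dict, velocity: dict, lr: float, mom: float) -> None:
    for name, g in grads.items():
        if isinstance(g, list):
            for k in range(len(g)):
                velocity[name][k] = mom * velocity[name][k] - lr * g[k]
                getattr(params, name)[k] += velocity[name][k]
        else:
            velocity[name] = mom * velocity[name] - lr * g
            arr = getattr(params, name)
            arr += velocity[name]


def fit(
    dataset: MolecularDataset,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> tuple[ModelParams, EnergyScaler, TrainHistory]:
    """Train a network on the dataset's train split, early-stopping on val MAE.

    Returns the parameters from the epoch with the lowest validation MAE
    (checkpoint-best early stopping).  Fully deterministic for a fixed
    seed: batch shuffling is reseeded each epoch from the master seed.
    """
    for split in ("train", "val"):
        if split not in dataset.splits or len(dataset.splits[split]) == 0:
            raise ValueError(f"dataset needs a nonempty {split!r} split")
    train = dataset.subset("train")
    val = dataset.subset("val")
    scaler = fit_energy_stats(train)
    params = init_params(
        dataset.charges_present(),
        model_cfg.grid.n_features,
        B=model_cfg.B, F=model_cfg.F, H=model_cfg.H, T=model_cfg.T,
        cutoff=model_cfg.cutoff, tied=model_cfg.tied, act=model_cfg.act,
        seed=train_cfg.seed, embedding_sd=model_cfg.embedding_sd,
    )
    train_pack = make_batch(train.molecules, params, model_cfg.grid)
    val_pack = make_batch(val.molecules, params, model_cfg.grid)

    velocity = zero_grads(params)
    history = TrainHistory()
    best_params = params.copy()
    n = len(train_pack)
    for epoch in range(train_cfg.epochs):
        rng = np.random.default_rng([train_cfg.seed, epoch])
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, train_cfg.batch_size):
            idx = perm[start : start + train_cfg.batch_size]
            loss, grads, _ = loss_and_grads(params, train_pack.take(idx), scaler)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {n_batches} "
                    f"(learning rate too high?)"
                )
            _sgd_step(params, grads, velocity, train_cfg.learning_rate, train_cfg.momentum)
            epoch_loss += loss
            n_batches += 1
        E_val, _ = forward_batch(params, val_pack, scaler)
        val_mae = float(np.mean(np.abs(E_val - val_pack.E_ref)))
        history.train_loss.append(epoch_loss / n_batches)
        history.val_mae.append(val_mae)
        history.epochs_run = epoch + 1
        if val_mae < history.best_val_mae:
            history.best_val_mae = val_mae
            history.best_epoch = epoch
            best_params = params.copy()
        if train_cfg.val_mae_target is not None and history.best_val_mae < train_cfg.val_mae_target:
            break
        if train_cfg.patience is not None and epoch - history.best_epoch >= train_cfg.patience:
            break
    return (best_params if train_cfg.restore_best else params), scaler, history


def predict_dataset(
    params: ModelParams,
    grid: GaussianGrid,
    scaler: EnergyScaler,
    dataset: MolecularDataset,
) -> np.ndarray:
    """Predicted molecular energies (kcal/mol), one per molecule."""
    pack = make_batch(dataset.molecules, params, grid, with_labels=False)
    E, _ = forward_batch(params, pack, scaler)
    return E


def evaluate_mae(
    params: ModelParams,
    grid: GaussianGrid,
    scaler: EnergyScaler,
    dataset: MolecularDataset,
) -> float:
    """Mean absolute error of predicted vs labelled energies (kcal/mol)."""
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty split")
    E = predict_dataset(params, grid, scaler, dataset)
    return float(np.mean(np.abs(E - dataset.energies())))


def thermal_energy(T: float) -> float:
    """k_B * T in kcal/mol (about 0.6 kcal/mol at room temperature)."""
    if T < 0:
        raise ValueError(f"temperature must be >= 0 K, got {T}")
    return BOLTZMANN_KCAL * T
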