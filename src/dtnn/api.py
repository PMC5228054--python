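"""High-level modelling interface.

Follows the model/results split common in statistical modelling packages:
:class:`DTNN` holds the data and the architecture specification; calling
:meth:`DTNN.fit` runs the optimizer and returns a :class:`DTNNResults`
carrying the trained parameters, the training history, evaluation metrics
and the interpretation tools (per-atom energies, probe grids, rankings).

Example
-------
>>> from dtnn import DTNN, synthetic
>>> data = synthetic.make_dataset(synthetic.default_spec(n_molecules=100))
>>> model = DTNN(data, n_passes=2)
>>> res = model.fit(epochs=200)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import analysis as _analysis
from .data import MoleculeGeometry, MolecularDataset, read_xyz, split_dataset
from .featurize import GaussianGrid
from .network import (
    EnergyScaler,
    ModelParams,
    load_checkpoint,
    molecular_energy,
    probe_energy,
    save_checkpoint,
)
from .training import (
    ModelConfig,
    TrainConfig,
    TrainHistory,
    evaluate_mae,
    fit as _fit,
    predict_dataset,
    thermal_energy,
)

__all__ = ["DTNN", "DTNNResults"]


class DTNN:
    """A deep tensor neural network potential specified on a dataset.

    Parameters
    ----------
    dataset : MolecularDataset
        Labelled molecules.  If it has no train/val/test splits yet they
        are assigned at fit time from ``split_fractions``.
    basis_size, n_factors, hidden : int
        Embedding width B, tensor-layer factors F, head hidden units H.
    n_passes : int
        Interaction passes T (1-3 are the useful range).
    cutoff : float, optional
        Hard interaction cutoff in A; ``None`` means all pairs interact.
    tied : bool
        Share interaction weights across passes (default) or not.
    grid : GaussianGrid, optional
        Distance expansion grid; defaults to centers -1..10 A at 0.2 A.
    """

    def __init__(
        self,
        dataset: MolecularDataset,
        *,
        basis_size: int = 30,
        n_factors: int = 60,
        hidden: int = 15,
        n_passes: int = 2,
        cutoff: float | None = None,
        tied: bool = True,
        act: str = "tanh",
        grid: GaussianGrid | None = None,
        split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
        split_seed: int = 0,
    ) -> None:
        self.dataset = dataset
        self.split_fractions = split_fractions
        self.split_seed = split_seed
        self.config = ModelConfig(
            B=basis_size, F=n_factors, H=hidden, T=n_passes,
            cutoff=cutoff, tied=tied, act=act,
            grid=grid if grid is not None else GaussianGrid(),
        )

    @classmethod
    def from_xyz(cls, path: str | Path, dialect: str = "plain", **kwargs) -> "DTNN":
        """Build a model directly from an extended-XYZ file."""
        reader_kw = {
            k: kwargs.pop(k) for k in ("property_column", "property_unit") if k in kwargs
        }
        return cls(read_xyz(path, dialect, **reader_kw), **kwargs)

    def fit(
        self,
        *,
        learning_rate: float = 1e-3,
        momentum: float = 0.9,
        epochs: int = 3000,
        batch_size: int = 32,
        seed: int = 0,
        patience: int | None = None,
        val_mae_target: float | None = None,
    ) -> "DTNNResults":
        """Train by constant-rate SGD with momentum; return checkpoint-best results."""
        data = self.dataset
        if not data.splits:
            data = split_dataset(data, self.split_fractions, seed=self.split_seed)
            self.dataset = data
        train_cfg = TrainConfig(
            learning_rate=learning_rate, momentum=momentum, epochs=epochs,
            batch_size=batch_size, seed=seed, patience=patience,
            val_mae_target=val_mae_target,
        )
        params, scaler, history = _fit(data, self.config, train_cfg)
        return DTNNResults(self, params, scaler, history, train_cfg)


class DTNNResults:
    """Fitted network: estimates, diagnostics and interpretation tools."""

    def __init__(
        self,
        model: DTNN | None,
        params: ModelParams,
        scaler: EnergyScaler,
        history: TrainHistory | None,
        train_cfg: TrainConfig | None = None,
        grid: GaussianGrid | None = None,
    ) -> None:
        self.model = model
        self.params = params
        self.scaler = scaler
        self.history = history
        self.train_cfg = train_cfg
        self.grid = grid if grid is not None else (
            model.config.grid if model is not None else GaussianGrid()
        )

    # -- prediction -------------------------------------------------------

    def predict(self, data: MolecularDataset | MoleculeGeometry) -> np.ndarray | float:
        """Molecular energies in kcal/mol (scalar for a single molecule)."""
        if isinstance(data, MoleculeGeometry):
            E, _ = molecular_energy(data, self.params, self.grid, self.scaler)
            return E
        return predict_dataset(self.params, self.grid, self.scaler, data)

    def atomic_energies(self, mol: MoleculeGeometry) -> np.ndarray:
        """The per-atom partition of the predicted energy (sums to predict(mol))."""
        _, E_i = molecular_energy(mol, self.params, self.grid, self.scaler)
        return E_i

    def mae(self, split: str = "test") -> float:
        """MAE in kcal/mol on one split of the model's dataset."""
        if self.model is None:
            raise ValueError("results were loaded without a dataset; pass data explicitly")
        return evaluate_mae(
            self.params, self.grid, self.scaler, self.model.dataset.subset(split)
        )

    # -- interpretation ---------------------------------------------------

    def probe_energy(self, mol: MoleculeGeometry, probe_Z: int, r) -> float:
        return probe_energy(mol, probe_Z, r, self.params, self.grid, self.scaler)

    def chemical_potential_grid(
        self, mol: MoleculeGeometry, probe_Z: int, origin, spacing, shape
    ) -> _analysis.ProbeResult:
        return _analysis.chemical_potential_grid(
            mol, probe_Z, origin, spacing, shape, self.params, self.grid, self.scaler
        )

    def substructure_energy(self, mol: MoleculeGeometry, atom_indices):
        return _analysis.substructure_energy(
            mol, self.atomic_energies(mol), atom_indices
        )

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of architecture, fit and errors."""
        p, lines = self.params, []
        n_par = p.embedding.size + sum(
            a.size for blk in (p.W_cf, p.b_f1, p.W_df, p.b_f2, p.W_fc) for a in blk
        ) + p.head_W1.size + p.head_b1.size + p.head_W2.size + p.head_b2.size
        lines.append("Deep Tensor Neural Network Results")
        lines.append("=" * 50)
        rows = [
            ("embedding width B", p.B),
            ("factors F", p.F),
            ("head hidden H", p.H),
            ("interaction passes T", p.n_passes),
            ("distance features G", p.G),
            ("cutoff (A)", p.cutoff if p.cutoff is not None else "none"),
            ("tied interaction weights", p.tied),
            ("species", ",".join(str(z) for z in p.charges)),
            ("parameters", n_par),
            ("E_mu (kcal/mol/atom)", f"{self.scaler.E_mu:.4f}"),
            ("E_sigma (kcal/mol/atom)", f"{self.scaler.E_sigma:.4f}"),
        ]
        if self.history is not None:
            rows += [
                ("epochs run", self.history.epochs_run),
                ("best epoch", self.history.best_epoch),
                ("best val MAE (kcal/mol)", f"{self.history.best_val_mae:.4f}"),
                (
                    "best val MAE / kT(300 K)",
                    f"{self.history.best_val_mae / thermal_energy(300.0):.2f}",
                ),
            ]
        if self.model is not None and "test" in self.model.dataset.splits:
            rows.append(("test MAE (kcal/mol)", f"{self.mae('test'):.4f}"))
        width = max(len(k) for k, _ in rows)
        for k, v in rows:
            lines.append(f"{k:<{width}}  {v}")
        lines.append("=" * 50)
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        cfg = {}
        if self.train_cfg is not None:
            cfg = {
                "learning_rate": self.train_cfg.learning_rate,
                "momentum": self.train_cfg.momentum,
                "epochs": self.train_cfg.epochs,
                "batch_size": self.train_cfg.batch_size,
                "seed": self.train_cfg.seed,
            }
        return save_checkpoint(path, self.params, self.grid, self.scaler, cfg)

    @classmethod
    def load(cls, path: str | Path) -> "DTNNResults":
        params, grid, scaler, _cfg = load_checkpoint(path)
        return cls(None, params, scaler, None, None, grid=grid)
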