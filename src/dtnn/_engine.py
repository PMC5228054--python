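"""Padded-batch forward/backward engine.

Training needs many thousands of gradient steps, so molecules are packed
into padded arrays (batch, N_max, ...) with boolean masks and the whole
forward and backward pass is expressed as einsums over the batch.  The
readable per-molecule operations in :mod:`dtnn.network` are the reference
semantics; a test pins this engine to them.

Gradients are hand-derived backpropagation (no autodiff dependency) and
are validated against central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import MoleculeGeometry, distance_matrix
from .featurize import GaussianGrid, expand_all
from .network import EnergyScaler, ModelParams, activation, activation_grad

__all__ = ["PaddedBatch", "make_batch", "forward_batch", "loss_and_grads",
           "zero_grads", "flatten_params", "unflatten_into"]


@dataclass
class PaddedBatch:
    """Molecules padded to a common atom count, with masks."""

    rows: np.ndarray       # (M, Nmax) int64 embedding-row indices (0 on padding)
    atom_mask: np.ndarray  # (M, Nmax) float64, 1 on real atoms
    feats: np.ndarray      # (M, Nmax, Nmax, G) Gaussian-expanded distances
    pair_mask: np.ndarray  # (M, Nmax, Nmax) float64: j acts on i (cutoff applied)
    E_ref: np.ndarray | None  # (M,) labels, kcal/mol
    n_atoms: np.ndarray    # (M,)

    def __len__(self) -> int:
        return self.rows.shape[0]

    def take(self, idx: np.ndarray) -> "PaddedBatch":
        return PaddedBatch(
            rows=self.rows[idx],
            atom_mask=self.atom_mask[idx],
            feats=self.feats[idx],
            pair_mask=self.pair_mask[idx],
            E_ref=None if self.E_ref is None else self.E_ref[idx],
            n_atoms=self.n_atoms[idx],
        )


def make_batch(
    mols: Sequence[MoleculeGeometry],
    params: ModelParams,
    grid: GaussianGrid,
    *,
    with_labels: bool = True,
) -> PaddedBatch:
    """Pack molecules into padded arrays; features are computed once here."""
    M = len(mols)
    if M == 0:
        raise ValueError("empty batch")
    n_atoms = np.array([m.n_atoms for m in mols], dtype=np.int64)
    Nmax = int(n_atoms.max())
    G = grid.n_features
    rows = np.zeros((M, Nmax), dtype=np.int64)
    atom_mask = np.zeros((M, Nmax))
    feats = np.zeros((M, Nmax, Nmax, G))
    pair_mask = np.zeros((M, Nmax, Nmax))
    E_ref = np.empty(M) if with_labels else None
    for m, mol in enumerate(mols):
        n = mol.n_atoms
        rows[m, :n] = [params.row(z) for z in mol.Z]
        atom_mask[m, :n] = 1.0
        D = distance_matrix(mol)
        feats[m, :n, :n] = expand_all(D, grid)
        pm = ~np.eye(n, dtype=bool)
        if params.cutoff is not None:
            pm &= D <= params.cutoff
        pair_mask[m, :n, :n] = pm
        if with_labels:
            if mol.energy is None:
                raise ValueError(f"molecule {m} has no energy label")
            E_ref[m] = mol.energy
    return PaddedBatch(rows, atom_mask, feats, pair_mask, E_ref, n_atoms)


def _rows(x: np.ndarray) -> np.ndarray:
    """Collapse all leading axes so the last axis becomes gemm columns."""
    return x.reshape(-1, x.shape[-1])


def forward_batch(
    params: ModelParams,
    batch: PaddedBatch,
    scaler: EnergyScaler,
    *,
    keep_cache: bool = False,
):
    """Batched forward pass.

    Returns ``(E, cache)`` where ``E`` is the (M,) vector of molecular
    energies in kcal/mol; ``cache`` holds the intermediates the backward
    pass needs (None unless requested).
    """
    g = activation(params.act)
    M, Nmax = batch.rows.shape
    C = params.embedding[batch.rows]                       # (M, N, B)
    passes = []
    dist_factor_by_block: dict[int, np.ndarray] = {}
    for t in range(params.n_passes):
        k = params.block(t)
        if k not in dist_factor_by_block:
            # one big gemm over all (molecule, pair) rows
            dist_factor_by_block[k] = (
                _rows(batch.feats) @ params.W_df[k].T + params.b_f2[k]
            ).reshape(M, Nmax, Nmax, -1)                             # (M,N,N,F)
        DF = dist_factor_by_block[k]
        AF = _rows(C) @ params.W_cf[k].T + params.b_f1[k]
        AF = AF.reshape(M, Nmax, -1)                                 # (M,N,F)
        pre = (_rows(AF[:, None, :, :] * DF) @ params.W_fc[k].T).reshape(
            M, Nmax, Nmax, -1
        )                                                            # (M,N,N,B)
        V = g(pre)
        C_next = C + (V * batch.pair_mask[..., None]).sum(axis=2)
        if keep_cache:
            passes.append({"C": C, "AF": AF, "k": k, "pre": pre})
        C = C_next
    opre = C @ params.head_W1.T + params.head_b1                      # (M,N,H)
    O = g(opre)
    ehat = (O @ params.head_W2.T + params.head_b2)[..., 0]            # (M,N)
    E_i = (scaler.E_sigma * ehat + scaler.E_mu) * batch.atom_mask
    E = E_i.sum(axis=1)
    cache = None
    if keep_cache:
        cache = {
            "passes": passes,
            "C_final": C,
            "opre": opre,
            "O": O,
            "dist_factor_by_block": dist_factor_by_block,
        }
    return E, cache


def zero_grads(params: ModelParams) -> dict:
    n_blocks = 1 if params.tied else params.n_passes
    return {
        "embedding": np.zeros_like(params.embedding),
        "W_cf": [np.zeros_like(params.W_cf[min(k, len(params.W_cf) - 1)]) for k in range(n_blocks)],
        "b_f1": [np.zeros_like(params.b_f1[0]) for _ in range(n_blocks)],
        "W_df": [np.zeros_like(params.W_df[0]) for _ in range(n_blocks)],
        "b_f2": [np.zeros_like(params.b_f2[0]) for _ in range(n_blocks)],
        "W_fc": [np.zeros_like(params.W_fc[0]) for _ in range(n_blocks)],
        "head_W1": np.zeros_like(params.head_W1),
        "head_b1": np.zeros_like(params.head_b1),
        "head_W2": np.zeros_like(params.head_W2),
        "head_b2": np.zeros_like(params.head_b2),
    }


def backward_batch(
    params: ModelParams,
    batch: PaddedBatch,
    cache: dict,
    dE: np.ndarray,
    scaler: EnergyScaler,
) -> dict:
    """Backpropagate dL/dE (shape (M,)) into gradients w.r.t. all parameters."""
    gp = activation_grad(params.act)
    grads = zero_grads(params)

    # --- energy head
    dehat = dE[:, None] * batch.atom_mask * scaler.E_sigma            # (M,N)
    O, opre, C = cache["O"], cache["opre"], cache["C_final"]
    grads["head_W2"] += (dehat.ravel() @ _rows(O))[None, :]
    grads["head_b2"] += np.array([dehat.sum()])
    dO = dehat[..., None] * params.head_W2[0]                          # (M,N,H)
    dopre = dO * gp(opre)
    grads["head_W1"] += _rows(dopre).T @ _rows(C)
    grads["head_b1"] += dopre.sum(axis=(0, 1))
    dC = dopre @ params.head_W1                                        # (M,N,B)

    # --- interaction passes, in reverse
    for t in range(params.n_passes - 1, -1, -1):
        p = cache["passes"][t]
        k = p["k"]
        C_t, AF, pre = p["C"], p["AF"], p["pre"]
        DF = cache["dist_factor_by_block"][k]
        dV = dC[:, :, None, :] * batch.pair_mask[..., None]            # (M,N,N,B)
        dpre = dV * gp(pre)
        P = AF[:, None, :, :] * DF
        grads["W_fc"][k] += _rows(dpre).T @ _rows(P)
        dP = (_rows(dpre) @ params.W_fc[k]).reshape(P.shape)           # (M,N,N,F)
        dAF = (dP * DF).sum(axis=1)                                    # (M,N,F), sum over i
        dDF = dP * AF[:, None, :, :]
        grads["W_cf"][k] += _rows(dAF).T @ _rows(C_t)
        grads["b_f1"][k] += dAF.sum(axis=(0, 1))
        grads["W_df"][k] += _rows(dDF).T @ _rows(batch.feats)
        grads["b_f2"][k] += dDF.sum(axis=(0, 1, 2))
        dC = dC + dAF @ params.W_cf[k]                                 # skip + factor path

    np.add.at(grads["embedding"], batch.rows, dC * batch.atom_mask[..., None])
    return grads


def loss_and_grads(
    params: ModelParams,
    batch: PaddedBatch,
    scaler: EnergyScaler,
) -> tuple[float, dict, np.ndarray]:
    """Standardized squared-error loss and its parameter gradients.

    The objective is mean_m ((E_m - E_m^ref) / E_sigma)^2 — the plain
    batch-summed squared error divided by the constant M * E_sigma^2, so
    it has the same minimizer but a learning-rate scale that is stable
    across datasets with very different absolute energies.  The returned
    residuals are in kcal/mol.
    """
    if batch.E_ref is None:
        raise ValueError("batch has no labels")
    E, cache = forward_batch(params, batch, scaler, keep_cache=True)
    resid = E - batch.E_ref
    M = len(batch)
    loss = float(np.mean((resid / scaler.E_sigma) ** 2))
    dE = 2.0 * resid / (M * scaler.E_sigma**2)
    grads = backward_batch(params, batch, cache, dE, scaler)
    return loss, grads, resid


# ---------------------------------------------------------------------------
# Flatten/unflatten (finite-difference checks, optimizer state)


def _walk(tree):
    for name in ("embedding", "W_cf", "b_f1", "W_df", "b_f2", "W_fc",
                 "head_W1", "head_b1", "head_W2", "head_b2"):
        node = tree[name] if isinstance(tree, dict) else getattr(tree, name)
        if isinstance(node, list):
            for k, arr in enumerate(node):
                yield f"{name}[{k}]", arr
        else:
            yield name, arr if (arr := node) is not None else node


def flatten_params(tree) -> np.ndarray:
    """Concatenate all parameter (or gradient) arrays into one vector."""
    return np.concatenate([arr.ravel() for _, arr in _walk(tree)])


def unflatten_into(params: ModelParams, vec: np.ndarray) -> None:
    """Write a flat vector back into the parameter arrays, in place."""
    pos = 0
    for _, arr in _walk(params):
        n = arr.size
        arr[...] = vec[pos : pos + n].reshape(arr.shape)
        pos += n
    if pos != vec.size:
        raise ValueError(f"vector length {vec.size} != parameter count {pos}")
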