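"""The deep tensor neural network forward computation.

Architecture
------------
Each atom i starts from a learnable per-element embedding c_i^(0) of
length B.  T interaction passes refine the embeddings:

    c_i^(t+1) = c_i^(t) + sum_{j != i} v_ij,
    v_ij = g( W_fc [ (W_cf c_j^(t) + b_f1) o (W_df dhat_ij + b_f2) ] ),

where dhat_ij is the Gaussian distance expansion of D_ij, "o" is the
element-wise product and g a bounded nonlinearity (tanh by default).
This is a low-rank factorization of the bilinear tensor layer

    v_ij[k] = g( b_k + (W_c c_j)_k + (W_d dhat_ij)_k + c_j^T V_k dhat_ij ),

which is kept here (``interaction_full``) as an explicit oracle.  After
the final pass a two-layer head maps each refined embedding to a scaled
atomic energy, which is de-standardized by the training-set per-atom
mean/s.d. and summed into the molecular energy — making the prediction
permutation invariant and size extensive by construction.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .data import MoleculeGeometry, distance_matrix
from .featurize import GaussianGrid, expand_all, gaussian_expand

__all__ = [
    "ModelParams",
    "OracleTensorParams",
    "EnergyScaler",
    "AtomicState",
    "init_params",
    "embed",
    "interaction_factorized",
    "interaction_full",
    "refine_pass",
    "atomic_energies",
    "molecular_energy",
    "probe_energy",
    "probe_energies",
    "forward_states",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Nonlinearities (value and derivative; the derivative feeds backprop)

_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
}


def activation(name: str) -> Callable[[np.ndarray], np.ndarray]:
    if name not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {name!r}; known: {sorted(_ACTIVATIONS)}")
    return _ACTIVATIONS[name][0]


def activation_grad(name: str) -> Callable[[np.ndarray], np.ndarray]:
    return _ACTIVATIONS[name][1]


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class ModelParams:
    """All learnable tensors plus the architecture hyperparameters.

    Interaction weights are stored as lists with one entry per weight
    block: a single shared block when ``tied`` (the default — one
    interaction module applied T times), or T independent blocks.
    """

    charges: tuple[int, ...]          # embeddable nuclear charges, row order
    embedding: np.ndarray             # (n_species, B)
    W_cf: list[np.ndarray]            # (F, B) per block
    b_f1: list[np.ndarray]            # (F,)
    W_df: list[np.ndarray]            # (F, G)
    b_f2: list[np.ndarray]            # (F,)
    W_fc: list[np.ndarray]            # (B, F)
    head_W1: np.ndarray               # (H, B)
    head_b1: np.ndarray               # (H,)
    head_W2: np.ndarray               # (1, H)
    head_b2: np.ndarray               # (1,)
    n_passes: int = 2
    cutoff: float | None = None
    tied: bool = True
    act: str = "tanh"
    _z_to_row: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._z_to_row:
            self._z_to_row = {int(z): i for i, z in enumerate(self.charges)}
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be > 0 when set")
        n_blocks = 1 if self.tied else self.n_passes
        for name in ("W_cf", "b_f1", "W_df", "b_f2", "W_fc"):
            if len(getattr(self, name)) != n_blocks:
                raise ValueError(f"{name} must have {n_blocks} block(s)")

    @property
    def B(self) -> int:
        return self.embedding.shape[1]

    @property
    def F(self) -> int:
        return self.W_cf[0].shape[0]

    @property
    def G(self) -> int:
        return self.W_df[0].shape[1]

    @property
    def H(self) -> int:
        return self.head_W1.shape[0]

    def block(self, t: int) -> int:
        """Weight-block index used by pass t (0-based)."""
        return 0 if self.tied else t

    def row(self, z: int) -> int:
        try:
            return self._z_to_row[int(z)]
        except KeyError:
            raise KeyError(
                f"nuclear charge Z={int(z)} not in the embedding table "
                f"(known: {list(self.charges)})"
            ) from None

    def copy(self) -> "ModelParams":
        return ModelParams(
            charges=self.charges,
            embedding=self.embedding.copy(),
            W_cf=[w.copy() for w in self.W_cf],
            b_f1=[b.copy() for b in self.b_f1],
            W_df=[w.copy() for w in self.W_df],
            b_f2=[b.copy() for b in self.b_f2],
            W_fc=[w.copy() for w in self.W_fc],
            head_W1=self.head_W1.copy(),
            head_b1=self.head_b1.copy(),
            head_W2=self.head_W2.copy(),
            head_b2=self.head_b2.copy(),
            n_passes=self.n_passes,
            cutoff=self.cutoff,
            tied=self.tied,
            act=self.act,
        )


@dataclass
class OracleTensorParams:
    """Explicit bilinear tensor-layer parameters (test oracle only)."""

    V: np.ndarray    # (B_out, B_in, G): slice V_k per output coefficient
    W_c: np.ndarray  # (B_out, B_in)
    W_d: np.ndarray  # (B_out, G)
    b: np.ndarray    # (B_out,)

    def __post_init__(self) -> None:
        Bo, Bi, G = self.V.shape
        if self.W_c.shape != (Bo, Bi) or self.W_d.shape != (Bo, G) or self.b.shape != (Bo,):
            raise ValueError("inconsistent oracle tensor shapes")


@dataclass(frozen=True)
class EnergyScaler:
    """Per-atom energy standardization estimated on the training set.

    The head predicts a dimensionless per-atom contribution which is
    de-standardized as E_i = E_sigma * Ehat_i + E_mu, so a zero-initialized
    output layer starts every atom at the training-set mean.
    """

    E_mu: float = 0.0
    E_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.E_sigma <= 0:
            raise ValueError("E_sigma must be > 0")


@dataclass
class AtomicState:
    """Per-atom coefficient vectors after ``t`` interaction passes."""

    coeffs: np.ndarray  # (N, B)
    t: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coefficient vectors must be finite")


# ---------------------------------------------------------------------------
# Initialization


def _glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    fan_out, fan_in = shape
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(
    charges: Sequence[int],
    n_features: int,
    *,
    B: int = 30,
    F: int = 60,
    H: int = 15,
    T: int = 2,
    cutoff: float | None = None,
    tied: bool = True,
    act: str = "tanh",
    seed: int = 0,
    embedding_sd: float | None = None,
) -> ModelParams:
    """Randomly initialize all parameters from one integer seed.

    Embeddings are N(0, sd) with sd = 1/sqrt(B) by default; weight
    matrices are Glorot-uniform; all biases and the output layer head_W2
    are zero, so the untrained model predicts the per-atom mean energy.
    """
    activation(act)  # validate early
    charges = tuple(sorted({int(z) for z in charges}))
    if any(z < 1 for z in charges):
        raise ValueError("nuclear charges must be >= 1")
    rng = np.random.default_rng(seed)
    sd = embedding_sd if embedding_sd is not None else 1.0 / np.sqrt(B)
    n_blocks = 1 if tied else T
    G = int(n_features)
    return ModelParams(
        charges=charges,
        embedding=rng.normal(0.0, sd, size=(len(charges), B)),
        W_cf=[_glorot_uniform(rng, (F, B)) for _ in range(n_blocks)],
        b_f1=[np.zeros(F) for _ in range(n_blocks)],
        W_df=[_glorot_uniform(rng, (F, G)) for _ in range(n_blocks)],
        b_f2=[np.zeros(F) for _ in range(n_blocks)],
        W_fc=[_glorot_uniform(rng, (B, F)) for _ in range(n_blocks)],
        head_W1=_glorot_uniform(rng, (H, B)),
        head_b1=np.zeros(H),
        head_W2=np.zeros((1, H)),
        head_b2=np.zeros(1),
        n_passes=T,
        cutoff=cutoff,
        tied=tied,
        act=act,
    )


# ---------------------------------------------------------------------------
# Forward operations


def embed(Z: Sequence[int], params: ModelParams) -> AtomicState:
    """Initial coefficient vectors: row i is the embedding of charge Z_i."""
    rows = np.array([params.row(z) for z in Z], dtype=np.int64)
    return AtomicState(coeffs=params.embedding[rows].copy(), t=0)


def interaction_factorized(
    c_j: np.ndarray, dhat: np.ndarray, params: ModelParams, block: int = 0
) -> np.ndarray:
    """Factorized interaction v_ij of atom j on atom i at expanded distance dhat."""
    k = block
    atom_factor = params.W_cf[k] @ c_j + params.b_f1[k]
    dist_factor = params.W_df[k] @ dhat + params.b_f2[k]
    g = activation(params.act)
    return g(params.W_fc[k] @ (atom_factor * dist_factor))


def interaction_full(
    c_j: np.ndarray,
    dhat: np.ndarray,
    oracle: OracleTensorParams,
    act: str = "tanh",
) -> np.ndarray:
    """Explicit bilinear tensor layer (the full-rank oracle form).

    Component k is g(b_k + (W_c c_j)_k + (W_d dhat)_k + c_j^T V_k dhat).
    """
    bilinear = np.einsum("a,kab,b->k", c_j, oracle.V, dhat)
    g = activation(act)
    return g(oracle.b + oracle.W_c @ c_j + oracle.W_d @ dhat + bilinear)


def _pair_mask(D: np.ndarray, cutoff: float | None) -> np.ndarray:
    """Boolean (N, N) mask of interacting ordered pairs (j acting on i)."""
    mask = ~np.eye(D.shape[0], dtype=bool)
    if cutoff is not None:
        mask &= D <= cutoff
    return mask


def refine_pass(
    state: AtomicState,
    D: np.ndarray,
    feats: np.ndarray,
    params: ModelParams,
) -> AtomicState:
    """One interaction pass: c_i += sum over in-range j != i of v_ij."""
    N = state.coeffs.shape[0]
    if D.shape != (N, N) or feats.shape[:2] != (N, N):
        raise ValueError("inconsistent atom counts across state, D and feats")
    k = params.block(state.t)
    g = activation(params.act)
    # vectorized over all pairs: atom factor depends on j only
    atom_factor = state.coeffs @ params.W_cf[k].T + params.b_f1[k]          # (N, F)
    dist_factor = feats @ params.W_df[k].T + params.b_f2[k]                 # (N, N, F)
    v = g((atom_factor[None, :, :] * dist_factor) @ params.W_fc[k].T)       # (N, N, B)
    mask = _pair_mask(D, params.cutoff)
    new = state.coeffs + np.einsum("ijb,ij->ib", v, mask.astype(np.float64))
    return AtomicState(coeffs=new, t=state.t + 1)


def atomic_energies(
    state: AtomicState, params: ModelParams, scaler: EnergyScaler
) -> np.ndarray:
    """Per-atom energies (kcal/mol) from final coefficient vectors."""
    g = activation(params.act)
    o = g(state.coeffs @ params.head_W1.T + params.head_b1)        # (N, H)
    ehat = o @ params.head_W2.T + params.head_b2                   # (N, 1)
    return scaler.E_sigma * ehat[:, 0] + scaler.E_mu


def forward_states(
    mol: MoleculeGeometry,
    params: ModelParams,
    grid: GaussianGrid,
) -> list[AtomicState]:
    """All coefficient states c^(0) .. c^(T) of a molecule (probe input)."""
    D = distance_matrix(mol)
    feats = expand_all(D, grid)
    states = [embed(mol.Z, params)]
    for _ in range(params.n_passes):
        states.append(refine_pass(states[-1], D, feats, params))
    return states


def molecular_energy(
    mol: MoleculeGeometry,
    params: ModelParams,
    grid: GaussianGrid,
    scaler: EnergyScaler,
) -> tuple[float, np.ndarray]:
    """Total molecular energy and its per-atom partition (kcal/mol).

    Runs embed -> T refinement passes -> energy head; the total is the
    plain sum of atomic contributions.
    """
    state = forward_states(mol, params, grid)[-1]
    E_i = atomic_energies(state, params, scaler)
    return float(E_i.sum()), E_i


# ---------------------------------------------------------------------------
# Probe atom / local chemical potential


def probe_energies(
    mol: MoleculeGeometry,
    probe_Z: int,
    positions: np.ndarray,
    params: ModelParams,
    grid: GaussianGrid,
    scaler: EnergyScaler,
    states: list[AtomicState] | None = None,
) -> np.ndarray:
    """Energy of a probe atom of charge ``probe_Z`` at each position (P, 3).

    The coupling is one-way: the molecule's coefficient states are computed
    once without the probe (or supplied precomputed) and the probe vector is
    refined T times against the molecule's pass-t coefficients using the
    probe-atom distances.  The molecule is never influenced by the probe.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    if positions.shape[1] != 3:
        raise ValueError("positions must have shape (P, 3)")
    if not np.all(np.isfinite(positions)):
        raise ValueError("probe positions must be finite")
    if states is None:
        states = forward_states(mol, params, grid)
    P = positions.shape[0]
    d = np.linalg.norm(positions[:, None, :] - mol.R[None, :, :], axis=2)  # (P, N)
    feats = np.exp(-grid.exponent * (d[..., None] - grid.centers) ** 2)    # (P, N, G)
    in_range = (
        np.ones_like(d, dtype=bool) if params.cutoff is None else d <= params.cutoff
    )
    g = activation(params.act)
    p = np.tile(params.embedding[params.row(probe_Z)], (P, 1))             # (P, B)
    for t in range(params.n_passes):
        k = params.block(t)
        atom_factor = states[t].coeffs @ params.W_cf[k].T + params.b_f1[k]  # (N, F)
        dist_factor = feats @ params.W_df[k].T + params.b_f2[k]             # (P, N, F)
        v = g((atom_factor[None, :, :] * dist_factor) @ params.W_fc[k].T)   # (P, N, B)
        p = p + np.einsum("pnb,pn->pb", v, in_range.astype(np.float64))
    o = g(p @ params.head_W1.T + params.head_b1)
    ehat = o @ params.head_W2.T + params.head_b2
    return scaler.E_sigma * ehat[:, 0] + scaler.E_mu


def probe_energy(
    mol: MoleculeGeometry,
    probe_Z: int,
    r: np.ndarray,
    params: ModelParams,
    grid: GaussianGrid,
    scaler: EnergyScaler,
    states: list[AtomicState] | None = None,
) -> float:
    """Local chemical potential: probe energy at a single position (kcal/mol)."""
    return float(
        probe_energies(mol, probe_Z, np.asarray(r, dtype=float).reshape(1, 3),
                       params, grid, scaler, states)[0]
    )


# ---------------------------------------------------------------------------
# Checkpointing (single .npz archive; schema version in the JSON header)

_CHECKPOINT_SCHEMA = 1


def save_checkpoint(
    path: str | Path,
    params: ModelParams,
    grid: GaussianGrid,
    scaler: EnergyScaler,
    config: dict | None = None,
) -> Path:
    """Write all model arrays + grid + scaler + config into one .npz file."""
    path = Path(path)
    meta = {
        "schema": _CHECKPOINT_SCHEMA,
        "charges": list(params.charges),
        "n_passes": params.n_passes,
        "cutoff": params.cutoff,
        "tied": params.tied,
        "act": params.act,
        "grid": {
            "mu_min": grid.mu_min,
            "mu_max": grid.mu_max,
            "delta_mu": grid.delta_mu,
            "sigma": grid.sigma,
            "gamma": grid.gamma,
        },
        "scaler": {"E_mu": scaler.E_mu, "E_sigma": scaler.E_sigma},
        "config": config or {},
    }
    arrays: dict[str, np.ndarray] = {
        "embedding": params.embedding,
        "head_W1": params.head_W1,
        "head_b1": params.head_b1,
        "head_W2": params.head_W2,
        "head_b2": params.head_b2,
    }
    for name in ("W_cf", "b_f1", "W_df", "b_f2", "W_fc"):
        for k, arr in enumerate(getattr(params, name)):
            arrays[f"{name}_{k}"] = arr
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path) -> tuple[ModelParams, GaussianGrid, EnergyScaler, dict]:
    with np.load(Path(path), allow_pickle=False) as f:
        meta = json.loads(bytes(f["meta"]).decode())
        if meta["schema"] != _CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
        n_blocks = 1 if meta["tied"] else meta["n_passes"]
        params = ModelParams(
            charges=tuple(meta["charges"]),
            embedding=f["embedding"],
            W_cf=[f[f"W_cf_{k}"] for k in range(n_blocks)],
            b_f1=[f[f"b_f1_{k}"] for k in range(n_blocks)],
            W_df=[f[f"W_df_{k}"] for k in range(n_blocks)],
            b_f2=[f[f"b_f2_{k}"] for k in range(n_blocks)],
            W_fc=[f[f"W_fc_{k}"] for k in range(n_blocks)],
            head_W1=f["head_W1"],
            head_b1=f["head_b1"],
            head_W2=f["head_W2"],
            head_b2=f["head_b2"],
            n_passes=meta["n_passes"],
            cutoff=meta["cutoff"],
            tied=meta["tied"],
            act=meta["act"],
        )
    g = meta["grid"]
    grid = GaussianGrid(
        mu_min=g["mu_min"], mu_max=g["mu_max"], delta_mu=g["delta_mu"],
        sigma=g["sigma"], gamma=g["gamma"],
    )
    scaler = EnergyScaler(E_mu=meta["scaler"]["E_mu"], E_sigma=meta["scaler"]["E_sigma"])
    return params, grid, scaler, meta["config"]
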