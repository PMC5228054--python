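"""Interpretation instruments for trained networks.

Three tools built on the atomic energy partition the architecture provides
by construction:

* local chemical potential grids — the energy a probe atom of a chosen
  species would have on a regular 3-D grid of positions around a molecule,
  with strictly one-way coupling (the molecule never feels the probe);
  exported as Gaussian cube files;
* the molecular-shape scalar field g(r) = sum_i ||r - r_i||^-2 (units
  1/A^2) whose isosurface (default level 3.8 1/A^2) is the conventional
  surface on which the potential is displayed;
* substructure stability scores — sums of per-atom energies over
  caller-chosen atom subsets (e.g. a carbon six-ring), with stable
  ranking to pick out the most and least stable examples in a corpus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .data import MoleculeGeometry, Z_TO_SYMBOL
from .featurize import GaussianGrid
from .network import EnergyScaler, ModelParams, forward_states, probe_energies

__all__ = [
    "ProbeResult",
    "SubstructureScore",
    "ISO_LEVEL_DEFAULT",
    "BOHR_PER_ANGSTROM",
    "chemical_potential_grid",
    "isosurface_field",
    "export_cube",
    "read_cube",
    "substructure_energy",
    "rank_by_substructure",
    "carbon_six_rings",
]

# Conventional display iso-level for the inverse-square shape field (1/A^2).
ISO_LEVEL_DEFAULT = 3.8
BOHR_PER_ANGSTROM = 1.0 / 0.52917721067


@dataclass
class ProbeResult:
    """Local chemical potential sampled on a regular grid."""

    probe_Z: int
    grid_origin: np.ndarray   # (3,) A
    grid_spacing: np.ndarray  # (3,) A, axis-aligned
    grid_shape: tuple[int, int, int]
    values: np.ndarray        # grid_shape array, kcal/mol
    molecule: MoleculeGeometry

    def __post_init__(self) -> None:
        self.grid_origin = np.asarray(self.grid_origin, dtype=float)
        self.grid_spacing = np.asarray(self.grid_spacing, dtype=float)
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if any(s < 1 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.values.shape != self.grid_shape:
            raise ValueError("values shape must equal grid_shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("probe values must be finite")

    def positions(self) -> np.ndarray:
        """All grid positions, shape (nx*ny*nz, 3), z fastest."""
        axes = [
            self.grid_origin[k] + self.grid_spacing[k] * np.arange(self.grid_shape[k])
            for k in range(3)
        ]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


def chemical_potential_grid(
    mol: MoleculeGeometry,
    probe_Z: int,
    origin: np.ndarray,
    spacing: np.ndarray | float,
    shape: tuple[int, int, int],
    params: ModelParams,
    grid: GaussianGrid,
    scaler: EnergyScaler,
) -> ProbeResult:
    """Probe energies on a regular grid (molecule states computed once)."""
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise ValueError(f"grid shape must be positive, got {shape}")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    result = ProbeResult(
        probe_Z=probe_Z,
        grid_origin=np.asarray(origin, dtype=float),
        grid_spacing=spacing,
        grid_shape=shape,
        values=np.zeros(shape),
        molecule=mol,
    )
    states = forward_states(mol, params, grid)  # once, reused for every point
    vals = probe_energies(mol, probe_Z, result.positions(), params, grid, scaler, states)
    result.values = vals.reshape(shape)
    return result


def isosurface_field(mol: MoleculeGeometry, r: np.ndarray) -> float:
    """Inverse-square shape field g(r) = sum_i ||r - r_i||^-2 (1/A^2)."""
    r = np.asarray(r, dtype=float).reshape(3)
    d = np.linalg.norm(mol.R - r, axis=1)
    if np.any(d < 1e-6):
        raise ValueError("position coincides with an atom (within 1e-6 A)")
    return float(np.sum(1.0 / d**2))


def isosurface_field_grid(mol: MoleculeGeometry, positions: np.ndarray) -> np.ndarray:
    """Vectorized shape field over (P, 3) positions."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    d2 = np.sum((positions[:, None, :] - mol.R[None, :, :]) ** 2, axis=2)
    if np.any(d2 < 1e-12):
        raise ValueError("a position coincides with an atom (within 1e-6 A)")
    return np.sum(1.0 / d2, axis=1)


# ---------------------------------------------------------------------------
# Gaussian cube I/O (coordinates in bohr per the format convention)


def export_cube(result: ProbeResult, path: str | Path, comment: str = "") -> Path:
    """Write a ProbeResult as a Gaussian cube file.

    Header follows the standard convention: two comment lines; atom count
    and origin; three axis lines (positive voxel counts => lengths in
    bohr); atom records; then values in z-fastest order, six per line.
    """
    path = Path(path)
    mol = result.molecule
    b = BOHR_PER_ANGSTROM
    lines = [
        f"local chemical potential, probe Z={result.probe_Z}, values kcal/mol "
        f"(coordinates in bohr). {comment}".rstrip(),
        "generated by dtnn",
        f"{mol.n_atoms:5d} {result.grid_origin[0]*b:12.6f} "
        f"{result.grid_origin[1]*b:12.6f} {result.grid_origin[2]*b:12.6f}",
    ]
    for k in range(3):
        ax = np.zeros(3)
        ax[k] = result.grid_spacing[k] * b
        lines.append(
            f"{result.grid_shape[k]:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}"
        )
    for z, r in zip(mol.Z, mol.R):
        lines.append(
            f"{int(z):5d} {float(z):12.6f} {r[0]*b:12.6f} {r[1]*b:12.6f} {r[2]*b:12.6f}"
        )
    flat = result.values.ravel()  # C order == z fastest for (nx, ny, nz)
    # 9 significant digits (vs the traditional 6) so values survive a
    # write -> read round trip to well under 1e-6
    for start in range(0, flat.size, 6):
        lines.append(" ".join(f"{v:16.8E}" for v in flat[start : start + 6]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_cube(path: str | Path) -> ProbeResult:
    """Read back a cube file written by :func:`export_cube`."""
    lines = Path(path).read_text().splitlines()
    n_atoms, *origin_b = lines[2].split()
    n_atoms = int(n_atoms)
    origin = np.array([float(x) for x in origin_b]) / BOHR_PER_ANGSTROM
    shape = []
    spacing = []
    for k in range(3):
        parts = lines[3 + k].split()
        shape.append(int(parts[0]))
        spacing.append(float(parts[1 + k]) / BOHR_PER_ANGSTROM)
    Z = np.empty(n_atoms, dtype=np.int64)
    R = np.empty((n_atoms, 3))
    for a in range(n_atoms):
        parts = lines[6 + a].split()
        Z[a] = int(parts[0])
        R[a] = [float(x) / BOHR_PER_ANGSTROM for x in parts[2:5]]
    values = np.fromstring(" ".join(lines[6 + n_atoms :]), sep=" ")
    probe_z_tok = lines[0].split("probe Z=")[1].split(",")[0] if "probe Z=" in lines[0] else "1"
    return ProbeResult(
        probe_Z=int(probe_z_tok),
        grid_origin=origin,
        grid_spacing=np.array(spacing),
        grid_shape=tuple(shape),
        values=values.reshape(shape),
        molecule=MoleculeGeometry(Z=Z, R=R),
    )


# ---------------------------------------------------------------------------
# Substructure stability


@dataclass(frozen=True)
class SubstructureScore:
    """Sum of per-atom energies over one atom subset of one molecule."""

    molecule_id: str
    atom_indices: tuple[int, ...]
    score: float  # kcal/mol


def substructure_energy(
    mol: MoleculeGeometry,
    atomic_energies: np.ndarray,
    atom_indices,
    molecule_id: str | None = None,
) -> SubstructureScore:
    """Score an atom subset by the sum of its atomic energy contributions."""
    idx = [int(i) for i in atom_indices]
    if len(set(idx)) != len(idx):
        raise ValueError(f"duplicate atom indices in {idx}")
    if any(i < 0 or i >= mol.n_atoms for i in idx):
        raise IndexError(f"atom index out of range 0..{mol.n_atoms - 1}: {idx}")
    score = float(np.sum(np.asarray(atomic_energies)[idx])) if idx else 0.0
    return SubstructureScore(
        molecule_id=molecule_id if molecule_id is not None else (mol.id or ""),
        atom_indices=tuple(idx),
        score=score,
    )


def rank_by_substructure(
    scores: list[SubstructureScore], k: int
) -> tuple[list[SubstructureScore], list[SubstructureScore]]:
    """The k lowest-energy (most stable) and k highest-energy substructures.

    Total order: score ascending, ties broken by molecule id; stable and
    deterministic, so equal-score corpora rank lexicographically.
    """
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} available scores")
    ordered = sorted(scores, key=lambda s: (s.score, s.molecule_id))
    return ordered[:k], list(reversed(ordered[-k:])) if k else ([], [])


def carbon_six_rings(mol: MoleculeGeometry, bonds) -> list[tuple[int, ...]]:
    """All-carbon 6-cycles from a caller-supplied bond list.

    Convenience for ring-stability scoring; no bond perception is done here
    — ``bonds`` is an iterable of (i, j) atom-index pairs.
    """
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    g.add_edges_from((int(i), int(j)) for i, j in bonds)
    rings = []
    for cycle in nx.simple_cycles(g, length_bound=6):
        if len(cycle) == 6 and all(mol.Z[i] == 6 for i in cycle):
            rings.append(tuple(sorted(cycle)))
    return sorted(set(rings))
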