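"""Molecular geometries, distance matrices and extended-XYZ I/O.

The package works on a deliberately small data model: a molecule is a
vector of nuclear charges ``Z`` and an ``(N, 3)`` array of Cartesian
coordinates in Angstrom, optionally carrying a scalar energy label.  All
energies inside the package are in kcal/mol; converters from Hartree and
eV are applied at ingest time only.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "MoleculeGeometry",
    "MolecularDataset",
    "SYMBOL_TO_Z",
    "Z_TO_SYMBOL",
    "HARTREE_TO_KCAL",
    "EV_TO_KCAL",
    "convert_energy",
    "read_xyz",
    "write_xyz",
    "distance_matrix",
    "split_dataset",
    "save_npz",
    "load_npz",
]

# Energy unit conversion factors into the internal unit (kcal/mol).
HARTREE_TO_KCAL = 627.509
EV_TO_KCAL = 23.0609

_UNIT_FACTORS = {
    "kcal/mol": 1.0,
    "kcal": 1.0,
    "hartree": HARTREE_TO_KCAL,
    "ha": HARTREE_TO_KCAL,
    "au": HARTREE_TO_KCAL,
    "ev": EV_TO_KCAL,
}

# Periodic table up to Kr; more than enough for organic chemistry datasets.
_SYMBOLS = (
    "H He "
    "Li Be B C N O F Ne "
    "Na Mg Al Si P S Cl Ar "
    "K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr"
).split()

SYMBOL_TO_Z = {s: i + 1 for i, s in enumerate(_SYMBOLS)}
Z_TO_SYMBOL = {i + 1: s for i, s in enumerate(_SYMBOLS)}


def convert_energy(value: float, unit: str) -> float:
    """Convert an energy from ``unit`` to kcal/mol."""
    key = unit.strip().lower()
    if key not in _UNIT_FACTORS:
        raise ValueError(f"unknown energy unit {unit!r}; known: {sorted(_UNIT_FACTORS)}")
    return value * _UNIT_FACTORS[key]


@dataclass(frozen=True)
class MoleculeGeometry:
    """A molecule: nuclear charges, Cartesian coordinates (A), optional label.

    Parameters
    ----------
    Z : array of int
        Nuclear charges, one per atom, each >= 1.
    R : array of float, shape (N, 3)
        Cartesian coordinates in Angstrom.
    energy : float, optional
        Energy label in kcal/mol.
    id : str, optional
        Free-form identifier (e.g. the source record name).
    """

    Z: np.ndarray
    R: np.ndarray
    energy: float | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        Z = np.asarray(self.Z, dtype=np.int64)
        R = np.asarray(self.R, dtype=np.float64)
        if Z.ndim != 1 or Z.size < 1:
            raise ValueError("Z must be a non-empty 1-D integer array")
        if R.shape != (Z.size, 3):
            raise ValueError(f"R must have shape ({Z.size}, 3), got {R.shape}")
        if np.any(Z < 1):
            raise ValueError("all nuclear charges must be >= 1")
        if not np.all(np.isfinite(R)):
            raise ValueError("coordinates must be finite")
        if self.energy is not None and not np.isfinite(self.energy):
            raise ValueError("energy label must be finite")
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "R", R)

    @property
    def n_atoms(self) -> int:
        return int(self.Z.size)

    def with_energy(self, energy: float) -> "MoleculeGeometry":
        return replace(self, energy=float(energy))

    def symbols(self) -> list[str]:
        return [Z_TO_SYMBOL[int(z)] for z in self.Z]


@dataclass
class MolecularDataset:
    """An ordered collection of molecules with optional train/val/test splits.

    ``splits`` maps each split name to an index array into ``molecules``;
    together the index arrays partition the collection.
    """

    molecules: list[MoleculeGeometry]
    splits: dict[str, np.ndarray] = field(default_factory=dict)
    unit: str = "kcal/mol"

    def __post_init__(self) -> None:
        if self.splits:
            idx = np.concatenate([np.asarray(v, dtype=np.int64) for v in self.splits.values()]) \
                if self.splits else np.empty(0, dtype=np.int64)
            if sorted(idx.tolist()) != list(range(len(self.molecules))):
                raise ValueError("split indices must partition the dataset")
            self.splits = {k: np.asarray(v, dtype=np.int64) for k, v in self.splits.items()}

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self) -> Iterator[MoleculeGeometry]:
        return iter(self.molecules)

    def __getitem__(self, i: int) -> MoleculeGeometry:
        return self.molecules[i]

    def subset(self, split: str) -> "MolecularDataset":
        """Return the molecules of one split as a new (split-less) dataset."""
        if split not in self.splits:
            raise KeyError(f"no split named {split!r}; have {sorted(self.splits)}")
        mols = [self.molecules[i] for i in self.splits[split]]
        return MolecularDataset(mols, unit=self.unit)

    def energies(self) -> np.ndarray:
        """Energy labels as an array; raises if any molecule is unlabelled."""
        out = np.empty(len(self.molecules))
        for k, m in enumerate(self.molecules):
            if m.energy is None:
                raise ValueError(f"molecule {k} ({m.id!r}) has no energy label")
            out[k] = m.energy
        return out

    def charges_present(self) -> list[int]:
        zs: set[int] = set()
        for m in self.molecules:
            zs.update(int(z) for z in m.Z)
        return sorted(zs)


def distance_matrix(mol: MoleculeGeometry) -> np.ndarray:
    """Pairwise Euclidean distance matrix in Angstrom.

    Symmetric with zero diagonal; depends only on the internal geometry,
    hence invariant under rotations, translations and reflections.
    """
    diff = mol.R[:, None, :] - mol.R[None, :, :]
    D = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    # enforce exact symmetry/zero diagonal against floating-point noise
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# Extended-XYZ I/O


class XYZParseError(ValueError):
    pass


_ENERGY_RE = re.compile(r"energy\s*=\s*([-+0-9.eEdD]+)")


def _parse_symbol_or_charge(token: str, record: int) -> int:
    if token in SYMBOL_TO_Z:
        return SYMBOL_TO_Z[token]
    try:
        z = int(token)
    except ValueError:
        raise XYZParseError(
            f"record {record}: unknown element symbol {token!r}"
        ) from None
    if z < 1:
        raise XYZParseError(f"record {record}: nuclear charge must be >= 1, got {z}")
    return z


def read_xyz(
    path: str | Path,
    dialect: str = "plain",
    *,
    property_column: int = 0,
    property_unit: str = "kcal/mol",
) -> MolecularDataset:
    """Read a (multi-record) extended-XYZ file.

    Parameters
    ----------
    dialect : {"plain", "gdb9"}
        ``plain`` looks for an ``energy=<value>`` token (kcal/mol) in the
        comment line.  ``gdb9`` treats the comment line as a whitespace/tab
        separated property list and maps ``property_column`` (0-based) to
        the energy label, converting from ``property_unit`` to kcal/mol.
        GDB-9 deposits prefix the property list with a tag and an index;
        ``property_column`` counts over the numeric fields only.
    """
    if dialect not in ("plain", "gdb9"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = Path(path).read_text()
    lines = text.splitlines()
    mols: list[MoleculeGeometry] = []
    pos = 0
    record = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise XYZParseError(
                f"record {record}: expected atom count, got {lines[pos]!r}"
            ) from None
        if n < 1:
            raise XYZParseError(f"record {record}: atom count must be >= 1, got {n}")
        if pos + 1 + n >= len(lines) + 1 and pos + 1 + n > len(lines):
            raise XYZParseError(
                f"record {record}: file ends before {n} atom lines"
            )
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        Z = np.empty(n, dtype=np.int64)
        R = np.empty((n, 3))
        for a in range(n):
            li = pos + 2 + a
            if li >= len(lines):
                raise XYZParseError(f"record {record}: file ends before {n} atom lines")
            parts = lines[li].split()
            if len(parts) < 4:
                # count line of the next record reached too early, or junk
                raise XYZParseError(
                    f"record {record}: atom line {a} has {len(parts)} fields, need >= 4"
                )
            Z[a] = _parse_symbol_or_charge(parts[0], record)
            try:
                R[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise XYZParseError(
                    f"record {record}: non-numeric coordinate in atom line {a}: "
                    f"{lines[li]!r}"
                ) from None
        energy = _extract_energy(comment, dialect, property_column, property_unit, record)
        mols.append(MoleculeGeometry(Z=Z, R=R, energy=energy, id=f"record{record}"))
        pos += 2 + n
        record += 1
    return MolecularDataset(mols)


def _extract_energy(
    comment: str, dialect: str, column: int, unit: str, record: int
) -> float | None:
    if dialect == "plain":
        m = _ENERGY_RE.search(comment)
        if m is None:
            return None
        return float(m.group(1).replace("D", "e").replace("d", "e"))
    # gdb9: whitespace/tab separated property list; keep numeric fields only
    numeric: list[float] = []
    for tok in comment.split():
        try:
            numeric.append(float(tok))
        except ValueError:
            continue
    if not numeric:
        return None
    if column >= len(numeric):
        raise XYZParseError(
            f"record {record}: property column {column} out of range "
            f"({len(numeric)} numeric fields)"
        )
    return convert_energy(numeric[column], unit)


def write_xyz(dataset: MolecularDataset | Iterable[MoleculeGeometry], path: str | Path) -> Path:
    """Write molecules as plain extended-XYZ (energy in the comment line)."""
    path = Path(path)
    out: list[str] = []
    for mol in dataset:
        out.append(str(mol.n_atoms))
        comment = "" if mol.energy is None else f"energy={mol.energy!r}"
        out.append(comment)
        for sym, (x, y, z) in zip(mol.symbols(), mol.R):
            out.append(f"{sym:2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    path.write_text("\n".join(out) + ("\n" if out else ""))
    return path


# ---------------------------------------------------------------------------
# Splitting


def split_dataset(
    dataset: MolecularDataset,
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> MolecularDataset:
    """Assign every molecule to train/validation/test by seeded permutation.

    Split sizes are the rounded fractions of the total (largest-remainder
    so they sum exactly); the same seed always yields the same assignment.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3:
        raise ValueError("fractions must be (train, val, test)")
    if any(f <= 0 for f in fractions):
        raise ValueError("all fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(dataset)
    if n < 3:
        raise ValueError(f"need at least 3 molecules to form 3 splits, have {n}")
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    remainders = [r - s for r, s in zip(raw, sizes)]
    while sum(sizes) < n:
        k = int(np.argmax(remainders))
        sizes[k] += 1
        remainders[k] = -1.0
    if min(sizes) < 1:
        raise ValueError(f"fractions {fractions} leave an empty split for n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    bounds = np.cumsum(sizes)
    splits = {
        "train": np.sort(perm[: bounds[0]]),
        "val": np.sort(perm[bounds[0] : bounds[1]]),
        "test": np.sort(perm[bounds[1] :]),
    }
    return MolecularDataset(list(dataset.molecules), splits=splits, unit=dataset.unit)


# ---------------------------------------------------------------------------
# Packed binary container (runtime convenience; never shipped in the repo)


def save_npz(dataset: MolecularDataset, path: str | Path) -> Path:
    """Pack a dataset into one .npz file (ragged arrays stored flat)."""
    path = Path(path)
    n_atoms = np.array([m.n_atoms for m in dataset.molecules], dtype=np.int64)
    Z = np.concatenate([m.Z for m in dataset.molecules]) if len(dataset) else np.empty(0, np.int64)
    R = (
        np.concatenate([m.R for m in dataset.molecules])
        if len(dataset)
        else np.empty((0, 3))
    )
    has_e = np.array([m.energy is not None for m in dataset.molecules])
    E = np.array([m.energy if m.energy is not None else np.nan for m in dataset.molecules])
    split_names = sorted(dataset.splits)
    np.savez(
        path,
        n_atoms=n_atoms,
        Z=Z,
        R=R,
        E=E,
        has_energy=has_e,
        split_names=np.array(split_names),
        **{f"split_{k}": dataset.splits[k] for k in split_names},
    )
    return path


def load_npz(path: str | Path) -> MolecularDataset:
    with np.load(path, allow_pickle=False) as f:
        n_atoms = f["n_atoms"]
        Z, R, E, has_e = f["Z"], f["R"], f["E"], f["has_energy"]
        offsets = np.concatenate([[0], np.cumsum(n_atoms)])
        mols = [
            MoleculeGeometry(
                Z=Z[offsets[i] : offsets[i + 1]],
                R=R[offsets[i] : offsets[i + 1]],
                energy=float(E[i]) if has_e[i] else None,
                id=f"record{i}",
            )
            for i in range(len(n_atoms))
        ]
        splits = {str(k): f[f"split_{k}"] for k in f["split_names"]}
    return MolecularDataset(mols, splits=splits)


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for run manifests."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
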