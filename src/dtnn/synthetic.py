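"""Seeded generators of labelled molecular datasets with known ground truth.

Real benchmark corpora (quantum-chemistry-labelled equilibrium databases
and ab initio MD trajectories) are not reproducible at desk scale, so the
test bed is built from two generators with analytic labels:

* random atom clusters scored by a pairwise Morse (or Lennard-Jones)
  potential — exactly pairwise-additive and distance-only, so a single
  interaction pass suffices in principle and every invariance the network
  must satisfy holds exactly for the labels;
* harmonic pseudo-MD: Gaussian displacements around a reference geometry
  labelled by an isotropic spring energy, emulating the statistical
  structure of configurational sampling without integrating dynamics.

Default species are H/C/O clusters with bond-scale Morse parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import MoleculeGeometry, MolecularDataset, distance_matrix, split_dataset

__all__ = [
    "PairParams",
    "SyntheticSpec",
    "default_spec",
    "random_cluster",
    "pair_potential_energy",
    "harmonic_trajectory",
    "make_dataset",
]


@dataclass(frozen=True)
class PairParams:
    """Parameters of one species-pair potential.

    Morse: D_e [ (1 - e^{-a (r - r_e)})^2 - 1 ]  (well depth D_e kcal/mol,
    equilibrium distance r_e A, stiffness a 1/A).  For Lennard-Jones the
    same fields are read as (epsilon, r_min, unused).
    """

    D_e: float
    r_e: float
    a: float = 2.0

    def __post_init__(self) -> None:
        if self.D_e <= 0 or self.r_e <= 0 or self.a <= 0:
            raise ValueError("pair-potential parameters must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a random-cluster dataset."""

    species: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 6: 0.3, 8: 0.2}
    )  # nuclear charge -> sampling weight
    n_atoms_min: int = 4
    n_atoms_max: int = 8
    box_size: float = 6.0       # A, cubic sampling box
    min_dist: float = 1.6       # A, hard-core radius: >= the largest pair r_e,
                                # so sampled pairs sit near/beyond equilibrium
                                # separation rather than on the repulsive wall
                                # (emulating equilibrium-structure statistics)
    potential: str = "morse"
    pair_params: dict[frozenset, PairParams] | None = None
    n_molecules: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_dist <= 0:
            raise ValueError("min_dist must be > 0")
        if self.box_size <= 2 * self.min_dist:
            raise ValueError("box_size must exceed 2 * min_dist")
        if self.n_atoms_min < 2 or self.n_atoms_max < self.n_atoms_min:
            raise ValueError("need n_atoms_max >= n_atoms_min >= 2")
        if self.potential not in ("morse", "lennard_jones"):
            raise ValueError(f"unknown potential {self.potential!r}")
        if not self.species or any(w <= 0 for w in self.species.values()):
            raise ValueError("species weights must be positive")

    def params_for(self, zi: int, zj: int) -> PairParams:
        table = self.pair_params if self.pair_params is not None else _default_pairs()
        key = frozenset((int(zi), int(zj)))
        if key not in table:
            raise KeyError(f"no pair parameters for species pair {sorted(key)}")
        return table[key]


# Bond-scale defaults for H/C/O: r_e from covalent-radius sums, well depths
# of tens of kcal/mol, Morse stiffness ~2 1/A — typical covalent-bond scales.
_COV_RADIUS = {1: 0.31, 6: 0.76, 8: 0.66}
_WELL_DEPTH = {1: 50.0, 6: 85.0, 8: 60.0}


def _default_pairs() -> dict[frozenset, PairParams]:
    out: dict[frozenset, PairParams] = {}
    zs = sorted(_COV_RADIUS)
    for i, zi in enumerate(zs):
        for zj in zs[i:]:
            out[frozenset((zi, zj)) if zi != zj else frozenset((zi,))] = PairParams(
                D_e=float(np.sqrt(_WELL_DEPTH[zi] * _WELL_DEPTH[zj])),
                r_e=_COV_RADIUS[zi] + _COV_RADIUS[zj],
                a=2.0,
            )
    return out


def default_spec(**overrides) -> SyntheticSpec:
    """The package's stated synthetic world; override fields by keyword."""
    return replace(SyntheticSpec(), **overrides) if overrides else SyntheticSpec()


def random_cluster(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> MoleculeGeometry:
    """One random cluster: uniform box positions with hard-core rejection."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = int(rng.integers(spec.n_atoms_min, spec.n_atoms_max + 1))
    zs = np.array(sorted(spec.species), dtype=np.int64)
    w = np.array([spec.species[int(z)] for z in zs])
    Z = rng.choice(zs, size=n, p=w / w.sum())
    R = np.empty((n, 3))
    placed = 0
    rejections = 0
    while placed < n:
        cand = rng.uniform(0.0, spec.box_size, size=3)
        if placed and np.any(np.linalg.norm(R[:placed] - cand, axis=1) < spec.min_dist):
            rejections += 1
            if rejections >= 10_000:
                raise RuntimeError(
                    f"packing infeasible: 10^4 consecutive rejections placing atom "
                    f"{placed} of {n} (box {spec.box_size} A, min_dist {spec.min_dist} A)"
                )
            continue
        R[placed] = cand
        placed += 1
        rejections = 0
    return MoleculeGeometry(Z=Z, R=R)


def pair_potential_energy(mol: MoleculeGeometry, spec: SyntheticSpec) -> float:
    """Analytic pairwise-additive ground-truth energy (kcal/mol)."""
    D = distance_matrix(mol)
    E = 0.0
    n = mol.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            p = spec.params_for(mol.Z[i], mol.Z[j])
            r = D[i, j]
            if spec.potential == "morse":
                E += p.D_e * ((1.0 - np.exp(-p.a * (r - p.r_e))) ** 2 - 1.0)
            else:  # lennard_jones: epsilon = D_e, r_min = r_e
                x = (p.r_e / r) ** 6
                E += p.D_e * (x * x - 2.0 * x)
    return float(E)


def harmonic_trajectory(
    ref: MoleculeGeometry,
    k_spring: float = 100.0,       # kcal/mol/A^2
    temperature_scale: float = 0.1,  # A, per-coordinate displacement s.d.
    n_frames: int = 100,
    seed: int = 0,
    *,
    spec: SyntheticSpec | None = None,
) -> MolecularDataset:
    """Gaussian-displaced frames of a reference geometry with spring labels.

    Each frame is ref + N(0, temperature_scale^2) per coordinate, labelled
    E = 1/2 k ||R - R_ref||^2; passing ``spec`` adds the pair-potential
    energy of the displaced frame on top (an anharmonic baseline).
    """
    if temperature_scale < 0 or k_spring < 0 or n_frames < 1:
        raise ValueError("k_spring, temperature_scale >= 0 and n_frames >= 1 required")
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        disp = rng.normal(0.0, temperature_scale, size=ref.R.shape) if temperature_scale else 0.0
        R = ref.R + disp
        E = 0.5 * k_spring * float(np.sum((R - ref.R) ** 2))
        mol = MoleculeGeometry(Z=ref.Z, R=R, id=f"frame{f}")
        if spec is not None:
            E += pair_potential_energy(mol, spec)
        frames.append(mol.with_energy(E))
    return MolecularDataset(frames)


def make_dataset(spec: SyntheticSpec) -> MolecularDataset:
    """n_molecules labelled clusters, pre-split 80/10/10 with the spec seed."""
    rng = np.random.default_rng(spec.seed)
    mols = []
    for m in range(spec.n_molecules):
        mol = random_cluster(spec, rng)
        mols.append(
            MoleculeGeometry(
                Z=mol.Z, R=mol.R,
                energy=pair_potential_energy(mol, spec),
                id=f"cluster{m}",
            )
        )
    return split_dataset(MolecularDataset(mols), (0.8, 0.1, 0.1), seed=spec.seed)
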