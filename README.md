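# dtnn — deep tensor neural network potentials

`dtnn` predicts molecular energies from nothing but nuclear charges **Z**
and interatomic distances *D*, using a deep tensor neural network: a
learned, size-extensive atomic decomposition E_M = Σᵢ Eᵢ in which every
atom's contribution comes from a coefficient vector that is repeatedly
refined by factorized pairwise interactions with its chemical
environment. Because the atomic partition exists by construction, the
same trained model doubles as an interpretation instrument: it assigns
stability scores to substructures (e.g. aromatic carbon rings) and maps
the *local chemical potential* Ω_M^A(**r**) — the energy a probe atom of
species A would have at position **r** near molecule M — onto volumetric
grids for visualization.

It is aimed at researchers in machine-learned interatomic potentials and
computational chemistry who want a small, dependency-light, fully
NumPy-based reference implementation with hand-derived, finite-difference
verified gradients.

## Model

1. **Embedding.** Each atom i starts from a learnable vector
   c_i⁽⁰⁾ = c_{Z_i} ∈ ℝᴮ (B = 30) shared by all atoms of the same element.
2. **Distance expansion.** Each distance D_ij is spread over a uniform
   grid of Gaussians, d̂_ij[k] = exp(−(D_ij − μ_k)²/2σ²), with centers
   from μ_min = −1 Å to μ_max in steps Δμ = 0.2 Å and σ = 0.2 Å.
3. **Interaction passes.** For t = 1..T (T = 1–3):

       c_i⁽ᵗ⁾ = c_i⁽ᵗ⁻¹⁾ + Σ_{j≠i} v_ij,
       v_ij = tanh( W^fc [ (W^cf c_j + b₁) ∘ (W^df d̂_ij + b₂) ] )

   The element-wise product of the two F = 60-dimensional factor
   projections is a low-rank factorization of the bilinear tensor layer
   v_ij[k] = g(b_k + (W^c c_j)_k + (W^d d̂_ij)_k + c_jᵀ V_k d̂_ij); the
   explicit full-rank form is kept in the code as a test oracle, and the
   test suite proves the two coincide under weight contraction.
4. **Energy head.** Two fully connected layers (15 hidden units) map each
   refined c_i⁽ᵀ⁾ to a standardized contribution, de-standardized by the
   training-set per-atom mean E_μ and s.d. E_σ and summed: E_M = Σᵢ Eᵢ.
   The prediction is exactly invariant to atom ordering and rigid motions,
   and additive over non-interacting fragments when a distance cutoff is set.

Training is plain mini-batch SGD with momentum 0.9 and a constant
learning rate, minimizing the squared energy error; the returned
parameters are from the epoch with the best validation MAE. Gradients
are hand-coded backpropagation (no autodiff dependency) and are checked
against central finite differences in the test suite.

Because quantum-chemistry-labelled corpora are not reproducible at desk
scale, the package ships seeded generators of random atom clusters
labelled by analytic pairwise Morse/Lennard-Jones potentials and of
harmonic pseudo-MD trajectories; these have exactly known ground truth
and exact invariances, so every claim the test suite makes is verifiable
from first principles.

## Worked example

```python
from dtnn import DTNN, synthetic

data = synthetic.make_dataset(synthetic.default_spec(n_molecules=200, seed=0))
model = DTNN(data, n_passes=2)
res = model.fit(epochs=200, seed=0)
print(res.summary())
```

```
Deep Tensor Neural Network Results
==================================================
embedding width B         30
factors F                 60
head hidden H             15
interaction passes T      2
distance features G       56
cutoff (A)                none
tied interaction weights  True
species                   1,6,8
parameters                7651
E_mu (kcal/mol/atom)      -8.3406
E_sigma (kcal/mol/atom)   7.2961
epochs run                200
best epoch                199
best val MAE (kcal/mol)   3.3351
best val MAE / kT(300 K)  5.59
test MAE (kcal/mol)       2.9613
==================================================
```

The scaler rows are the training-set per-atom energy statistics that
anchor the zero-initialized head; the MAE rows report held-out error in
kcal/mol and as a multiple of the thermal energy k_BT at room temperature
(0.596 kcal/mol), the conventional yardstick for a chemically useful
potential. Per-atom contributions and their sum:

```python
mol = data[0]
res.predict(mol)            # -37.054 kcal/mol (label: -36.481)
res.atomic_energies(mol)    # [-3.25, -0.84, -5.24, -12.34, -4.01, -2.02, -5.95, -3.39]
```

The probe-atom machinery exposes the learned interactions spatially:

```python
grid = res.chemical_potential_grid(mol, probe_Z=1, origin=(-2, -2, -2),
                                   spacing=0.5, shape=(20, 20, 20))
from dtnn.analysis import export_cube
export_cube(grid, "potential.cube")   # Gaussian cube, any viewer
```

The molecule is never influenced by the probe — its own energies are
bitwise identical before and after any probe computation.

## Command line

```bash
dtnn synth  -c config.yaml --seed 1 -o data/        # seeded synthetic dataset
dtnn train  data/dataset.xyz -c config.yaml -o run/ # checkpoint + history
dtnn predict run/checkpoint.npz data/dataset.xyz    # energy table
dtnn probe  run/checkpoint.npz mol.xyz --probe H -o probe/  # cube pair
dtnn eval   run/checkpoint.npz data/dataset.xyz     # MAE + kT yardstick
```

Every command writes a `manifest.json` (config, seed, input digests)
before its artifacts, so runs are reproducible from the manifest.

## Acceptance script

`scripts/acceptance.py` re-runs the package's core computation from
scratch: it generates the default 400-cluster Morse world from the given
seed, trains a two-pass network with the default optimizer, evaluates
held-out MAE against the label spread and the thermal-energy yardstick,
computes a hydrogen-probe chemical-potential grid, and writes the result
JSON to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `dtnn.data` — geometries, distance matrices, extended-XYZ I/O (plain
  and property-line dialects), seeded splits, unit conversion.
- `dtnn.featurize` — Gaussian distance expansion.
- `dtnn.network` — embeddings, factorized and full tensor layers,
  refinement passes, energy head, probe energies, checkpoints.
- `dtnn.training` — SGD with momentum, early stopping, metrics.
- `dtnn.analysis` — chemical potential grids, cube export, shape field,
  substructure stability scoring and ranking.
- `dtnn.synthetic` — cluster/trajectory generators with analytic labels.
- `dtnn.api` / `dtnn.cli` — the `DTNN`/`DTNNResults` interface and the
  `dtnn` command.

See `docs/methods.md` for the modelling assumptions, defaults and known
limitations.
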