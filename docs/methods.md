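# Methods

This note records the modelling choices behind `dtnn`: the network and
its assumptions, the parameters that matter and their defaults, what the
synthetic data generator does and does not emulate, the numerical
choices, and the limitations we know about. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The model and its assumptions

The network predicts a molecular energy as a sum of atomic
contributions, each a function of an atom-centered representation built
solely from nuclear charges and interatomic distances. The core
assumptions are:

- **Distance sufficiency.** A single interaction pass sees only pairwise
  distances; angular and higher-order geometric information enters
  indirectly, through repeated refinement (T ≥ 2 composes pairwise
  messages along walks of length T). Systems whose energetics depend on
  orientation at fixed pair distances need T ≥ 2 in this architecture.
- **Extensivity.** The energy is a per-atom sum, so it scales correctly
  with system size; with a finite interaction cutoff this becomes exact
  additivity over non-interacting fragments, which the suite checks to
  1e-9 relative.
- **Smoothness.** Gaussian distance features and tanh nonlinearities make
  the prediction C^∞ in the coordinates (forces are well-defined, though
  not implemented).

## Parameters, units, defaults

All energies are kcal/mol internally; Hartree (×627.509) and eV
(×23.0609) are converted at ingest. Coordinates are Å, atom indices
0-based.

| parameter | default | meaning / why |
|---|---|---|
| B | 30 | embedding width per atom |
| F | 60 | factors in the low-rank tensor layer |
| H | 15 | hidden units in the energy head |
| T | 2 | interaction passes; 1–3 is the useful range |
| μ_min, Δμ, σ | −1 Å, 0.2 Å, 0.2 Å | Gaussian distance grid; σ is a standard deviation (an exp(−γ(d−μ)²) parameterization with γ = 1/2σ² is available) |
| μ_max | 10 Å | covers the pair-distance range of small molecules; raise for larger systems |
| cutoff | none | all pairs interact (appropriate for small molecules); a hard cutoff (e.g. 3 Å) restores locality and extensivity for large ones |
| tied | true | one interaction module applied T times; untied per-pass weights are a flag |
| learning rate | 1e-3 | documented package default (see conditioning below), not a claim about any published setup |
| momentum | 0.9 | classical momentum |
| epochs | 3000 | fixed-length run with checkpoint-best early stopping |
| batch size | 32 | package default |

Initialization: embeddings N(0, 1/√B); weight matrices Glorot-uniform;
all biases and the head output layer zero, so the untrained model
predicts the training-set per-atom mean energy — a sensible starting
point that also makes several exact zero-propagation tests possible.

## Loss conditioning

The optimizer minimizes the mean over the batch of
((E_pred − E_ref)/E_σ)², where E_σ is the training-set per-atom energy
standard deviation. Up to the constant factor (batch size × E_σ²) this
is identical to the raw batch-summed squared error — same minimizer,
same SGD trajectory under a learning-rate rescale — but it gives the
default learning rate a stable meaning across datasets whose absolute
energies differ by orders of magnitude. Validation MAE and all reported
errors are in raw kcal/mol.

Early stopping is checkpoint-best: training runs its full budget and the
parameters from the epoch with the lowest validation MAE are returned.
A patience option can halt earlier, and `val_mae_target` halts as soon
as a requested validation error is reached. `restore_best=False`
returns final-epoch parameters instead — the right choice for capacity
diagnostics (overfitting a tiny set), where checkpoint-best would
otherwise return an early underfit snapshot selected by a noisy 2-point
validation split.

## The probe atom (local chemical potential)

The molecule's coefficient states c_j⁽⁰⁾..c_j⁽ᵀ⁾ are computed once,
without the probe. The probe starts from its species embedding and is
refined T times against the molecule's pass-t states using probe–atom
distances; its head energy is Ω_M^A(r). The coupling is strictly one
way — the molecule's own energies are bitwise unchanged by any probe
computation, which the suite asserts. Grids of probe energies are
exported as Gaussian cube files; for display, the conventional surface
is an isolevel (default 3.8 Å⁻²) of the inverse-square shape field
g(r) = Σᵢ ‖r − rᵢ‖⁻². That functional form is this package's
assumption — it is the only simple atom-sum with the right units — and
isosurface extraction itself is left to the visualization layer.

## The synthetic world

Real training corpora for this architecture are quantum-chemistry
labelled (equilibrium databases, ab initio MD) and cannot be regenerated
at desk scale, so all tests run on generators with analytic ground truth:

- **Random clusters** of H/C/O (weights 0.5/0.3/0.2), 4–8 atoms,
  uniformly placed in a 6 Å box with a hard-core rejection radius of
  1.6 Å, labelled by a pairwise Morse potential with per-pair well
  depths D_e = √(D_i D_j) from (H, C, O) = (50, 85, 60) kcal/mol,
  equilibrium distances r_e from covalent-radius sums, and stiffness
  a = 2 Å⁻¹ — covalent-bond energy and length scales. The hard core is
  set just above the largest r_e (C–C, 1.52 Å) deliberately: sampled
  pairs then sit in the near-equilibrium and attractive tail region,
  emulating the statistics of equilibrium-ish structures. Uniform boxes
  with a smaller core would instead sample deep repulsive-wall
  compressions (hundreds of kcal/mol) that no equilibrium or thermal
  dataset contains.
- **Harmonic pseudo-MD**: Gaussian coordinate displacements around a
  reference geometry (default s.d. 0.1 Å, a thermal-amplitude scale)
  labelled by an isotropic spring energy (default k = 100 kcal/mol/Å²),
  optionally plus the pair potential of the displaced frame.

What a green test establishes: the architecture can represent and
recover a strictly pairwise, distance-only energy surface from a few
hundred examples, with all its symmetries exact. What it does not
establish: performance on real quantum-chemical labels, many-body
effects, chemical diversity beyond three elements, or conformational
statistics of real MD. The Morse choice is intentional: an exactly
pairwise ground truth gives a mechanistic expectation (one pass suffices
in principle, a second must not hurt) rather than an unexplainable
benchmark number.

## Numerical choices

- The nonlinearity is tanh for both the interaction output and the head
  hidden layer (the architecture family calls for a bounded, odd,
  saturating g; g(0) = 0 makes zero-input annihilation exact);
  switchable via config.
- Gradients are hand-derived backpropagation through the padded-batch
  engine; the per-molecule operations are the reference semantics and
  the engine is pinned to them at 1e-12 relative (gemm blocking differs,
  so bitwise equality across batch shapes is not expected). Analytic
  gradients match central finite differences (step 1e-4) to better than
  1e-5 relative.
- The Gaussian-grid size count guards the floor with a 1e-9 absolute
  tolerance so binary representation of Δμ cannot drop the last center.
- Distance matrices are symmetrized and zeroed on the diagonal
  explicitly to keep exchange-symmetry tests exact.
- E_σ is floored at 1e-8 so constant-label (or single-molecule) training
  sets remain usable.
- Degenerate inputs: single-atom molecules are legal everywhere (empty
  interaction sums); empty datasets round-trip through XYZ I/O; probe
  positions may not coincide with an atom within 1e-6 Å for the shape
  field (true singularity).
- Cube files are written with 9 significant digits (vs the traditional
  6) so write→read round trips hold to 1e-6; coordinates follow the
  bohr convention with the unit flagged in the header comment.
- Ranking ties are broken by molecule id lexicographically, making
  substructure rankings a deterministic total order.

## Known limitations

- No forces, Hessians, periodic boundary conditions, charge or spin
  states.
- The training engine precomputes the full (N_mol, N_max, N_max, G)
  feature tensor in memory; fine for desk-scale corpora, not for 10⁵
  molecules.
- Constant learning rate SGD is the only optimizer by design; very stiff
  label distributions (e.g. repulsive-wall sampling) can defeat it.
- Aromatic/ring perception is out of scope: substructure scoring takes
  caller-supplied atom indices (with a convenience helper that finds
  all-carbon 6-cycles given a bond list).
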