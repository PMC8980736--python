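# Methods

## Problem and model

Docking engines estimate how tightly a small molecule binds a protein
pocket by sampling ligand conformations and scoring each pose with a
force-field-like energy function. `surrodock` replaces that sampling
with regression: a network maps a coarse, conformation-free description
of the pair — an 8-channel voxel image of the pocket and the ligand's
heavy-atom topology graph — to run-level summaries of what a docking
engine would have produced: seven statistics (mean, median, standard
deviation, minimum, maximum, skewness, excess kurtosis) of 13
interaction-energy terms, plus the binding affinity pK. Predicting
population parameters of the docking-energy distribution, rather than
the energy of any particular pose, is what makes the surrogate
conformation-agnostic: the optimal pose never appears in the input or
the output, so conformational sampling is implicit in the learned map.

The interaction energy convention is E_int = E(complex) − E(protein) −
E(ligand); the affinity convention is pK = −log₁₀(K/1 M) with K a
dissociation or inhibition constant (the two are treated identically),
so pK 8 corresponds to K ≈ 10 nM and larger pK means tighter binding.

## Featurization

**Pocket.** Protein atoms (standard amino-acid residues; waters always
excluded, other heteroatoms excluded by default but toggleable) within a
half-open cube [c−10 Å, c+10 Å)³ around the pocket center c are binned
into 2 Å voxels — index = ⌊(x − (c−10))/2⌋ per axis — and one-hot
encoded over (no atom, C, O, N, S, P, H, other). A voxel holding
several atom types sets every corresponding channel (channel-wise
maximum); channel 0 is set exactly when a voxel is empty, so the two
are complementary by construction. The center is the unweighted
centroid of the bound ligand's heavy atoms, or any explicit coordinate
for apo structures. The encoding is translation-equivariant but *not*
rotation-invariant; coordinates are used as deposited, with no
augmentation. Hydrogens are encoded when the file contains them; no
protonation is added. Alternate locations collapse to the
highest-occupancy record, ties keeping the first.

**Ligand.** Molecules are read with rdkit (default aromaticity
perception), hydrogens stripped. Atom rows use the order the parser
yields — no canonical ranking, so the encoding is permutation-sensitive
by design. If more than 36 heavy atoms remain, the atom with the
smallest total incident bond order is removed repeatedly, recomputing
after each removal; aromatic/conjugated bonds count 1.5 and ties go to
the lowest original index, making the loop deterministic. The 36-atom
cap aligns with drug-likeness: larger molecules usually break the
500 Da rule-of-five limit anyway. Disconnected fragments produced by
pruning (or present in salts) are retained. In the bond tensor the
aromatic/conjugated channel takes precedence over formal order, since
the two notions share one channel.

## Targets

Statistics use population (divisor-n) moments, skew m₃/m₂^1.5 and
excess kurtosis m₄/m₂² − 3, via scipy. When the sample variance is
below 10⁻¹² (constant samples, including single-iteration runs) std,
skew and kurtosis are defined as 0. The target vector is terms-major:
13 terms × 7 statistics, pK appended, length 92. Docking tables are
CSV, one row per iteration, one column per term; the term set is
configurable but must contain `E_without_VDWR` — the interaction energy
without repulsive van der Waals, the component that tracks experimental
affinity best. Columns that are identically zero are flagged inactive
(several force-field terms are, for typical inputs) but kept, so the
output layout never changes.

## Architecture and training

Each input passes through its own subnetwork — one projection layer to
width d, then (n−1) width-d layers — the two embeddings are
concatenated (2d) and processed by a third subnetwork of the same
depth, ending in a linear 91-output statistics head and a linear
1-output pK head. Every dense layer applies spectral normalization
(one power-iteration update per training step; the u/v vectors are
auxiliary state, not parameters), a bias, LeakyReLU (negative slope
0.3, configurable) and dropout 0.2; the shape-matched layers add
identity skip connections. This wiring reproduces the reference
parameter counts exactly — 45,618,267 (n=10, d=1024), 12,055,131
(6, 512), 4,913,499 (6, 256), pK head (d+1 parameters) excluded — which
is the evidence that the reconstruction is canonical. The published
count for the (10, 2048) variant is not consistent with any wiring that
matches the other three and is not used as a reference point here.

Training minimizes the mean over examples of the summed squared error
across all 92 outputs with Adam. The default learning rate is 10⁻⁶,
appropriate for raw (unstandardized) energy targets at full scale;
desk-scale synthetic runs use 10⁻³. Batch size defaults to 64, epochs
are bounded by config, and when a validation set is supplied early
stopping (patience 20) restores the best-validation parameters.
Initialization is Glorot-uniform from a seeded generator; construction,
shuffling and dropout all draw from seed-derived streams, so two runs
with one seed give bit-identical loss histories. Evaluation mode
disables dropout and freezes the spectral-norm state, making
predictions deterministic; in screening, duplicated molecules share one
prediction row so identical inputs get bit-identical outputs regardless
of batch position (dense-algebra batching is otherwise only
reproducible to accumulation-order precision, ~10⁻⁷ relative).

The network is implemented directly in NumPy (`surrodock.nn`):
spectral-norm dense layers with the standard fixed-(u,v) gradient,
manual backprop, Adam. Float32 parameters; losses accumulate in
float64.

Dataset splitting shuffles with a seed and takes ⌊0.7·N⌋ training
items by default — 3,875 complexes split 2,712/1,163 — with an optional
protein-disjoint mode that assigns whole protein groups to one side to
prevent target leakage between sets.

## The synthetic oracle

Real training data for this kind of surrogate requires months of
docking-engine CPU time on a curated affinity database. The package
instead ships a generator whose ground truth is known exactly, to make
recovery measurable:

* **Pockets**: 30–120 atoms uniform in the 20 Å cube, elements drawn
  from a fixed protein-like distribution (C 52 %, O 16 %, N 14 %,
  H 13 %, S 2 %, P 1 %, other 2 %).
* **Ligands**: 5–45 heavy atoms (so a fraction exercises pruning), a
  random spanning tree plus occasional ring-closing edges, bond orders
  and aromatic flags assigned without exceeding valence caps
  (C 4, N 3, O 2, F 1, S 6; aromatic counts 1.5).
* **Energy**: E_min = −(c_pᵀ W c_l)/s − v·b + μ₀, bilinear in the
  per-channel occupied-voxel counts c_p, atom-type counts c_l and
  bond-class counts b, with W ~ U[0,1)⁷ˣ⁶, v ~ U[0,0.5)⁴, s = 50,
  μ₀ = −10 kcal/mol. The bilinear form means exactly the information
  preserved by the featurization determines the target; with the
  default parameters E_min ≈ −36 ± 14 kcal/mol, the scale of real
  screening distributions.
* **Docking runs**: per-iteration samples are E_min + Gamma(2, 2) —
  nonnegative noise, so the run minimum is a consistent estimator of
  E_min, mimicking "best pose found improves with iterations". Default
  1,000 iterations per run. Seven companion terms are seeded affine
  transforms of the same samples plus Gaussian noise; five terms are
  identically zero, mirroring inactive force-field components. 13
  terms total.
* **Affinity**: pK = clip(−0.15·E_min + ε, 0, 14), ε ~ N(0, 0.3²) —
  a negative energy–affinity link (pK ≈ 5.3 ± 2.1) with measurement
  noise.

All randomness flows from one master seed through named substreams
(params/pocket/ligand/run/pK), so each stage is independently
reproducible.

What the generator does **not** emulate: real force-field physics and
energy correlations, realistic pocket geometry (atoms are uniform, not
on a protein backbone), chemically realistic ring systems and
functional groups, pose-dependent energies, or assay noise structure.
Passing the recovery test therefore shows the pipeline is wired
correctly end to end and that the architecture can learn a docking-like
composition→energy→affinity map at small scale; it does not certify
accuracy on real protein–ligand data, which requires retraining on
docking output at full scale (learning rate 10⁻⁶, the big
architectures, and a protein-disjoint split).

## Verification problem sizes

The test suite checks the parameter-count formula against direct
enumeration for the three reference architectures; statistics against
explicit Σ-loop formulas on 1,000 random vectors at 10⁻¹² relative
tolerance; voxelization against a per-atom scatter loop; and recovery
with 2,000 training / 500 held-out synthetic complexes and a 4-block,
width-64 network trained 100 epochs at learning rate 10⁻³ (fixed
seed), requiring held-out Pearson r ≥ 0.8 against the true minimum
E_without_VDWR and r ≥ 0.7 against the noiseless pK; the observed
values are ≈ 0.96 for both. These sizes were chosen to make the full
suite run in about two minutes on one CPU core while keeping the
recovery check statistically meaningful.

## Known limitations

* No rotation invariance: the pocket grid changes under rotation, and
  predictions with it. Rotational augmentation or an equivariant
  encoder are the standard remedies.
* Permutation sensitivity: the ligand tensors depend on rdkit's atom
  order.
* The pruning metric (sum of incident orders, aromatic = 1.5,
  lowest-index tie-break) is one deterministic reading of
  "least bond order"; Kekulé-integer and randomized-tie variants would
  give slightly different pruned graphs for large molecules.
* The fixed 13-term layout uses one required name (`E_without_VDWR`)
  plus placeholder force-field-style names; retraining against a real
  engine's output should substitute the engine's term names via the
  configurable term set.
* QED is intentionally not computed here; only Lipinski counts are
  reported. logP is taken from the library file when a column is
  present, otherwise computed with rdkit's Crippen estimator, and the
  provenance is recorded per record.
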