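# surrodock

A conformation-agnostic neural surrogate for protein–small-molecule
docking. Instead of sampling ligand poses, `surrodock` trains a fully
connected network to map a **coarse voxelized binding pocket** and a
**ligand topology graph** directly to run-level summaries of a docking
engine's output — the mean, median, standard deviation, minimum,
maximum, skewness and excess kurtosis of 13 interaction-energy terms —
plus the binding affinity pK. A single forward pass replaces thousands
of docking iterations, which makes ranking very large compound
libraries tractable on modest hardware.

It is aimed at computational chemists who already run a physics-based
docking engine and want a fast learned stand-in for triage-scale virtual
screening, and at method developers who need a fully testable
reimplementation of this class of surrogate.

## The model

Inputs:

* **Pocket** — protein atoms inside a 20 Å cube centered at the bound
  ligand (or any supplied coordinate), discretised as a
  10 × 10 × 10 grid of 2 Å voxels with an 8-channel one-hot occupancy
  encoding (no atom, C, O, N, S, P, H, other); co-resident atoms take
  the channel-wise maximum. Flattened: 8,000 values.
* **Ligand** — the heavy-atom graph only (no conformer): a 36 × 7
  one-hot atom-type matrix (no atom, C, N, O, F, S, other) and a
  36 × 36 × 5 one-hot bond-adjacency tensor (no bond, single, double,
  triple, aromatic/conjugated). Molecules over 36 heavy atoms are pruned
  by iteratively removing the atom with the least total bond order
  (aromatic = 1.5). Flattened: 6,732 values.

Architecture: a protein encoder and a ligand encoder (each *n* dense
layers of width *d*), concatenation, and an affinity predictor of the
same depth, ending in a 91-output statistics head and a 1-output pK
head. Every dense layer uses spectral normalization, LeakyReLU and
dropout 0.2; shape-matched layers carry identity skip connections. The
trainable-parameter count excluding the pK head is

    N(n, d) = (3(n−1) + 2)·d² + (8000 + 6732 + 91 + 3n)·d + 91,

giving 45,618,267 for (n=10, d=1024), 12,055,131 for (6, 512) and
4,913,499 for (6, 256). The loss is the summed squared error over all
92 outputs, optimized with Adam (default learning rate 10⁻⁶). pK is
−log₁₀(K/1 M) for a dissociation or inhibition constant K, treated
interchangeably — pK 8 ≈ 10 nM.

Because no docking engine is bundled, the package ships a synthetic
oracle (`surrodock.synthetic`) with a known bilinear ground-truth energy
and a negative energy–affinity link, so every stage — featurization,
target construction, training, screening — is exercised end to end with
measurable recovery. The network itself is implemented in NumPy
(`surrodock.nn`): spectral-norm dense layers, backprop and Adam in a few
hundred lines.

## Worked example

Train a small surrogate on 400 synthetic complexes, check held-out
recovery of the oracle's minimum E_without_VDWR, and screen a tiny
library:

```python
import numpy as np
from surrodock import model as md, synthetic as sy, screen as sc
from surrodock.pocket import voxelize

examples, truth = sy.make_dataset(500, seed=7, n_iter=200)
config = md.ModelConfig(n_blocks=4, hidden=64, learning_rate=1e-3,
                        epochs=40, batch_size=64, seed=7)
results = md.DockingSurrogate(examples[:400], config).fit(
    validation=examples[400:])
print(results.summary())

held = truth.iloc[400:]
xp = np.stack([e.pocket.flatten() for e in examples[400:]])
xl = np.stack([e.ligand.flatten() for e in examples[400:]])
corr = md.evaluate_correlation(results.predict_stat(xp, xl),
                               held.e_min.to_numpy())
print(f"held-out r(min E_without_VDWR) = {corr.r:.3f}")

pocket = voxelize(sy.make_pocket(99), np.zeros(3))
library = "CC(=O)Oc1ccccc1C(=O)O aspirin\nCCO ethanol\nc1ccccc1 benzene\n"
for rec in sc.screen(results, pocket, library):
    print(f"rank {rec.rank}  {rec.mol_id:8s} pred_pK={rec.pred_pk:.2f} "
          f"pred_min_E={rec.pred_min_e:.1f} "
          f"lipinski_violations={rec.lipinski_violations}")
```

Output:

```
Docking surrogate fit
======================================================
subnetwork depth (n_blocks)                          4
hidden width (d)                                    64
trainable parameters (with pK head)            994,652
dropout / LeakyReLU slope                    0.2 / 0.3
learning rate (Adam)                             0.001
training examples                                  400
validation examples                                100
epochs run                                          40
final training loss                            1290.67
best validation loss                           940.841
======================================================
held-out r(min E_without_VDWR) = 0.904
rank 0  aspirin  pred_pK=3.72 pred_min_E=-24.2 lipinski_violations=0
rank 1  ethanol  pred_pK=3.11 pred_min_E=-19.7 lipinski_violations=0
rank 2  benzene  pred_pK=3.08 pred_min_E=-19.6 lipinski_violations=0
```

The summary table reports the architecture, parameter count and losses;
`r = 0.904` says the surrogate's predicted minimum interaction energy
tracks the oracle's true minimum on complexes it never saw. The
screening records come back sorted by predicted pK (higher = predicted
tighter binder) with the predicted minimum E_without_VDWR (lower =
better) and Lipinski rule-of-five violation counts alongside.

The same workflow is available from the shell:

```bash
surrodock featurize --pdb complex.pdb --ligand-resname LIG --out pocket.npz
surrodock synth --n 2000 --seed 7 --out data.npz --truth truth.tsv
surrodock train --data data.npz --blocks 4 --hidden 64 --lr 1e-3 --out ckpt/
surrodock screen --model ckpt/ --pocket pocket.npz --smi library.smi \
    --top 100 --out hits.tsv
surrodock count-params --blocks 10 --hidden 1024
```

## Layout

| module | contents |
| --- | --- |
| `surrodock.pocket` | PDB reading, pocket selection, voxel encoding |
| `surrodock.ligand` | SMILES parsing, pruning, graph tensor encoding |
| `surrodock.targets` | energy statistics, pK conversion, table ingestion |
| `surrodock.nn` | spectral-norm dense layers, backprop, Adam (NumPy) |
| `surrodock.model` | architecture, training, splits, Model/Results API |
| `surrodock.synthetic` | ground-truth oracle and dataset generator |
| `surrodock.screen` | Lipinski filtering, batch screening, ranking |
| `surrodock.cli` | `surrodock` command-line entry points |

See `docs/methods.md` for the modelling assumptions, parameter choices
and limitations.
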