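"""Synthetic pockets, ligands, docking runs and affinities.

A stand-in docking oracle with a known ground truth, so featurization,
target construction, training and screening can be exercised end to end
at desk scale. The oracle's minimum interaction energy is bilinear in
the encoded compositions,

    E_min = -(c_p^T W c_l) / s  -  v . b  +  mu0,

where c_p counts occupied voxels per pocket element channel, c_l counts
ligand atoms per type channel and b counts bonds per class — so exactly
the information that survives the grid/graph featurization determines
the target, and a surrogate trained on the encodings can in principle
recover it. Per-iteration docking samples add nonnegative Gamma noise to
E_min, making the sample minimum a consistent estimator of the true
minimum (the best pose found improves with more iterations), and the
affinity follows a noisy negative-slope link pK = clip(a - b_pk E_min +
eps, 0, 14): lower (better) energies mean tighter binding.

All randomness flows from one master seed through named substreams, so
each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import targets as tg
from .ligand import Bond, LigandGraph, MoleculeGraph, encode_ligand, \
    prune_ligand
from .model import TrainingExample
from .pocket import Atom, PocketGrid, StructureAtoms, voxelize

__all__ = [
    "OracleParams",
    "make_pocket",
    "make_ligand",
    "oracle_energy",
    "sample_docking_run",
    "make_dataset",
    "N_ACTIVE_TERMS",
    "N_ZERO_TERMS",
]

#: element frequencies for synthetic pockets (heavy-atom protein
#: composition plus a partially protonated fraction)
_POCKET_ELEMENTS = ("C", "O", "N", "S", "P", "H", "FE")
_POCKET_FREQS = (0.52, 0.16, 0.14, 0.02, 0.01, 0.13, 0.02)

#: element frequencies for synthetic drug-like ligands
_LIGAND_ELEMENTS = ("C", "N", "O", "F", "S")
_LIGAND_FREQS = (0.72, 0.12, 0.12, 0.02, 0.02)
_VALENCE_CAPS = {"C": 4.0, "N": 3.0, "O": 2.0, "F": 1.0, "S": 6.0}
_DEFAULT_CAP = 4.0

# 8 active terms (E_without_VDWR + 7 affine companions), 5 identically zero
N_ACTIVE_TERMS = 8
N_ZERO_TERMS = 5

_SUBSTREAMS = {"params": 0, "pocket": 1, "ligand": 2, "run": 3, "pk": 4}


def _stream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _SUBSTREAMS[name], int(index)]))


@dataclass
class OracleParams:
    """Ground-truth energy oracle and noise model, derived from one seed."""

    W: np.ndarray          # (7, 6) pocket-channel x ligand-channel weights
    v: np.ndarray          # (4,) bond-class weights (single/double/triple/arom)
    scale: float = 50.0
    offset: float = -10.0  # kcal/mol baseline
    gamma_shape: float = 2.0
    gamma_scale: float = 2.0
    pk_intercept: float = 0.0
    pk_slope: float = 0.15   # pK = clip(a - slope * E_min + eps, 0, 14)
    pk_sigma: float = 0.3
    seed: int = 0
    # seeded affine maps producing the 7 companion energy terms
    term_alpha: np.ndarray = field(default=None)  # type: ignore[assignment]
    term_beta: np.ndarray = field(default=None)   # type: ignore[assignment]
    term_tau: np.ndarray = field(default=None)    # type: ignore[assignment]

    @classmethod
    def from_seed(cls, seed: int = 0) -> "OracleParams":
        rng = _stream(seed, "params")
        return cls(
            W=rng.random((7, 6)),
            v=rng.random(4) * 0.5,
            term_alpha=rng.uniform(0.2, 1.5, size=N_ACTIVE_TERMS - 1),
            term_beta=rng.uniform(-5.0, 5.0, size=N_ACTIVE_TERMS - 1),
            term_tau=rng.uniform(0.1, 1.0, size=N_ACTIVE_TERMS - 1),
            seed=seed,
        )

    def to_dict(self) -> dict:
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "OracleParams":
        d = dict(d)
        for k in ("W", "v", "term_alpha", "term_beta", "term_tau"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def make_pocket(seed: int, n_atoms: int | None = None) -> StructureAtoms:
    """Random protein-like pocket: atoms uniform in the 20 Å origin cube."""
    rng = _stream(seed, "pocket")
    if n_atoms is None:
        n_atoms = int(rng.integers(30, 121))
    coords = rng.uniform(-10.0, 10.0, size=(n_atoms, 3))
    elements = rng.choice(_POCKET_ELEMENTS, size=n_atoms, p=_POCKET_FREQS)
    atoms = [Atom(str(el), tuple(xyz), "protein")
             for el, xyz in zip(elements, coords)]
    return StructureAtoms(atoms)


def make_ligand(seed: int, n_atoms: int | None = None,
                extra_edge_prob: float = 0.15) -> MoleculeGraph:
    """Random heavy-atom molecular graph respecting valence caps.

    A random spanning tree guarantees connectivity; extra edges and bond
    upgrades (double/triple/aromatic) are added only where both endpoints
    have spare valence, counting aromatic bonds as 1.5. Sizes are drawn
    from [5, 45], so a fraction of molecules exceeds the 36-atom encoding
    limit and exercises pruning.
    """
    rng = _stream(seed, "ligand")
    if n_atoms is None:
        n_atoms = int(rng.integers(5, 46))
    # draw elements sequentially, forcing a carbon whenever the running
    # spare valence would drop below what the remaining atoms need — this
    # keeps the spanning tree constructible without exceeding any cap
    elements: list[str] = []
    spare_total = 0.0
    for i in range(n_atoms):
        el = str(rng.choice(_LIGAND_ELEMENTS, p=_LIGAND_FREQS))
        cap = _VALENCE_CAPS.get(el, _DEFAULT_CAP)
        cost = cap if i == 0 else cap - 2.0
        if i < n_atoms - 1 and spare_total + cost < 1.0:
            el, cap = "C", _VALENCE_CAPS["C"]
            cost = cap if i == 0 else cap - 2.0
        spare_total += cost
        elements.append(el)
    caps = np.array([_VALENCE_CAPS.get(e, _DEFAULT_CAP) for e in elements])
    used = np.zeros(n_atoms)
    bonds: list[Bond] = []
    bonded: set[tuple[int, int]] = set()

    def weight(order: int, aromatic: bool) -> float:
        return 1.5 if aromatic else float(order)

    def add_bond(i: int, j: int, order: int, aromatic: bool) -> None:
        bonds.append(Bond(i, j, order, aromatic))
        bonded.add((min(i, j), max(i, j)))
        used[i] += weight(order, aromatic)
        used[j] += weight(order, aromatic)

    # spanning tree: attach each atom to an earlier atom with spare valence
    for i in range(1, n_atoms):
        candidates = [j for j in range(i) if caps[j] - used[j] >= 1.0]
        parent = int(rng.choice(candidates))  # non-empty by construction
        add_bond(parent, i, 1, False)
    # occasional extra ring-closing edges
    n_extra = rng.binomial(n_atoms, extra_edge_prob)
    for _ in range(n_extra):
        free = [j for j in range(n_atoms) if caps[j] - used[j] >= 1.0]
        if len(free) < 2:
            break
        i, j = (int(x) for x in rng.choice(free, size=2, replace=False))
        if i == j or (min(i, j), max(i, j)) in bonded:
            continue
        add_bond(i, j, 1, False)
    # upgrade some single bonds where valence allows
    for k, b in enumerate(bonds):
        spare = min(caps[b.i] - used[b.i], caps[b.j] - used[b.j])
        roll = rng.random()
        if roll < 0.10 and spare >= 0.5:
            bonds[k] = Bond(b.i, b.j, 1, True)  # aromatic/conjugated, +0.5
            used[b.i] += 0.5
            used[b.j] += 0.5
        elif roll < 0.25 and spare >= 1.0:
            bonds[k] = Bond(b.i, b.j, 2, False)
            used[b.i] += 1.0
            used[b.j] += 1.0
        elif roll < 0.28 and spare >= 2.0:
            bonds[k] = Bond(b.i, b.j, 3, False)
            used[b.i] += 2.0
            used[b.j] += 2.0
    return MoleculeGraph(elements, bonds)


def oracle_energy(grid: PocketGrid, ligand: LigandGraph,
                  params: OracleParams) -> float:
    """Ground-truth minimum E_without_VDWR for an encoded pair."""
    c_p = grid.occupancy[..., 1:].sum(axis=(0, 1, 2)).astype(float)   # (7,)
    c_l = ligand.atom_types[:, 1:].sum(axis=0).astype(float)          # (6,)
    # per-class bond counts over unordered pairs (single/double/triple/arom)
    b = ligand.adjacency[..., 1:].sum(axis=(0, 1)).astype(float) / 2.0
    return float(-(c_p @ params.W @ c_l) / params.scale
                 - params.v @ b + params.offset)


def sample_docking_run(e_min: float, params: OracleParams, n_iter: int = 1000,
                       seed: int = 0) -> tg.EnergySamples:
    """Emulate one docking run of ``n_iter`` iterations (13 energy terms).

    E_without_VDWR samples are E_min plus nonnegative Gamma(k, theta)
    noise; seven companion terms are seeded affine transforms of those
    samples plus Gaussian noise; the remaining five terms are identically
    zero, mirroring force-field components inactive for typical inputs.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = _stream(params.seed, "run", seed)
    base = e_min + rng.gamma(params.gamma_shape, params.gamma_scale,
                             size=n_iter)
    samples = {tg.REQUIRED_TERM: base}
    for k in range(N_ACTIVE_TERMS - 1):
        noise = rng.normal(0.0, params.term_tau[k], size=n_iter)
        samples[tg.DEFAULT_TERM_NAMES[1 + k]] = (
            params.term_alpha[k] * base + params.term_beta[k] + noise)
    for name in tg.DEFAULT_TERM_NAMES[N_ACTIVE_TERMS:]:
        samples[name] = np.zeros(n_iter)
    return tg.EnergySamples(samples, tg.DEFAULT_TERM_NAMES)


def make_dataset(n: int, seed: int = 0, params: OracleParams | None = None,
                 n_iter: int = 1000, ligands_per_pocket: int = 1):
    """Generate ``n`` synthetic complexes plus their ground-truth table.

    Returns ``(examples, truth)`` where ``truth`` is a DataFrame with the
    oracle minimum energy ``e_min``, the noiseless affinity ``pk_true``
    and the noisy training affinity ``pk`` for every complex. Fully
    determined by ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or OracleParams.from_seed(seed)
    pk_rng = _stream(seed, "pk")
    examples: list[TrainingExample] = []
    rows = []
    for i in range(n):
        pocket_index = i // ligands_per_pocket
        pocket_atoms = make_pocket(seed * 1_000_003 + pocket_index)
        grid = voxelize(pocket_atoms, center=np.zeros(3))
        mol = make_ligand(seed * 1_000_003 + i)
        lig = encode_ligand(prune_ligand(mol))
        e_min = oracle_energy(grid, lig, params)
        run = sample_docking_run(e_min, params, n_iter=n_iter, seed=i)
        pk_true = float(np.clip(
            params.pk_intercept - params.pk_slope * e_min, 0.0, 14.0))
        pk_noisy = float(np.clip(
            params.pk_intercept - params.pk_slope * e_min
            + pk_rng.normal(0.0, params.pk_sigma), 0.0, 14.0))
        targets = tg.summarize_energies(run, pk=pk_noisy)
        protein_id = f"synthprot{pocket_index:06d}"
        complex_id = f"synthcplx{i:06d}"
        examples.append(TrainingExample(grid, lig, targets,
                                        protein_id, complex_id))
        rows.append({"complex_id": complex_id, "protein_id": protein_id,
                     "e_min": e_min, "pk_true": pk_true, "pk": pk_noisy,
                     "n_heavy_atoms": lig.n_atoms})
    return examples, pd.DataFrame(rows)
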