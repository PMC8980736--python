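"""Ligand topology encoding.

A small molecule is represented purely by its heavy-atom graph — no
conformer, no stereochemistry — as a 36 x 7 one-hot atom-type matrix over
(no atom, C, N, O, F, S, other) and a 36 x 36 x 5 one-hot bond-adjacency
tensor over (no bond, single, double, triple, aromatic/conjugated).
Molecules with more than 36 heavy atoms are pruned by iteratively removing
the atom with the least total bond order (aromatic bonds count 1.5), which
preserves ring systems and multiply-bonded cores at the expense of
peripheral single-bonded atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "Bond",
    "MoleculeGraph",
    "LigandGraph",
    "SmilesRecord",
    "parse_smiles",
    "iter_smiles_records",
    "atom_channel",
    "bond_channel",
    "total_bond_order",
    "prune_ligand",
    "encode_ligand",
    "MAX_ATOMS",
    "ATOM_CHANNELS",
    "BOND_CHANNELS",
    "LIGAND_FLAT_SIZE",
]

MAX_ATOMS = 36
#: atom-type channel order; index 0 is the padding channel
ATOM_CHANNELS = ("", "C", "N", "O", "F", "S", "other")
#: bond channel order; index 0 is "no bond"
BOND_CHANNELS = ("none", "single", "double", "triple", "aromatic")
LIGAND_FLAT_SIZE = MAX_ATOMS * 7 + MAX_ATOMS * MAX_ATOMS * 5  # 6732

_ATOM_TO_CHANNEL = {"C": 1, "N": 2, "O": 3, "F": 4, "S": 5}
#: weight of an aromatic/conjugated bond in the pruning metric
AROMATIC_ORDER = 1.5


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: int  # formal order 1, 2 or 3
    aromatic: bool = False

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("self-bonds are not allowed")
        if self.order not in (1, 2, 3):
            raise ValueError(f"unknown bond order {self.order!r}")


@dataclass
class MoleculeGraph:
    """Heavy-atom molecular graph: element symbols plus typed bonds."""

    elements: list[str]
    bonds: list[Bond] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        n = len(self.elements)
        for el in self.elements:
            if el.upper() == "H":
                raise ValueError("hydrogens must be removed from the graph")
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond {b} references a missing atom")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond for pair {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, i: int) -> list[int]:
        return [b.j if b.i == i else b.i for b in self.bonds
                if i in (b.i, b.j)]


@dataclass
class SmilesRecord:
    """One parsed line of a ZINC-style SMILES library."""

    smiles: str
    mol_id: str | None = None
    logp: float | None = None
    graph: MoleculeGraph | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.graph is not None


def _graph_from_rdkit(mol: Chem.Mol) -> MoleculeGraph:
    mol = Chem.RemoveHs(mol)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = []
    for b in mol.GetBonds():
        bt = b.GetBondType()
        aromatic = b.GetIsAromatic()
        if aromatic or bt == Chem.BondType.AROMATIC:
            order, aromatic = 1, True
        elif bt == Chem.BondType.SINGLE:
            order = 1
        elif bt == Chem.BondType.DOUBLE:
            order = 2
        elif bt == Chem.BondType.TRIPLE:
            order = 3
        else:
            raise ValueError(f"unsupported bond type {bt} in molecule")
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                          order, aromatic))
    return MoleculeGraph(elements, bonds)


def parse_smiles(line: str) -> SmilesRecord:
    """Parse one ``SMILES [id [logP]]`` line.

    Unparseable molecules yield a record with ``error`` set rather than
    raising, so a library stream can be filtered without aborting.
    """
    fields = line.split()
    if not fields:
        raise ValueError("empty SMILES line")
    smiles = fields[0]
    mol_id = fields[1] if len(fields) > 1 else None
    logp = None
    if len(fields) > 2:
        try:
            logp = float(fields[2])
        except ValueError:
            logp = None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return SmilesRecord(smiles, mol_id, logp, None, "rdkit parse failure")
    try:
        graph = _graph_from_rdkit(mol)
    except ValueError as exc:
        return SmilesRecord(smiles, mol_id, logp, None, str(exc))
    if graph.n_atoms == 0:
        return SmilesRecord(smiles, mol_id, logp, None, "no heavy atoms")
    return SmilesRecord(smiles, mol_id, logp, graph, None)


def iter_smiles_records(text: str):
    """Yield :class:`SmilesRecord` for each non-empty, non-comment line."""
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        yield parse_smiles(line)


def atom_channel(element: str) -> int:
    """Atom-type channel (C/N/O/F/S, else 6); hydrogens are rejected."""
    el = element.upper().strip()
    if not el:
        raise ValueError("empty element symbol")
    if el == "H":
        raise ValueError("hydrogens must be removed before encoding")
    return _ATOM_TO_CHANNEL.get(el, 6)


def bond_channel(bond: Bond) -> int:
    """Bond channel; the aromatic/conjugated flag wins over formal order."""
    if bond.aromatic:
        return 4
    return bond.order


def total_bond_order(mol: MoleculeGraph, index: int) -> float:
    """Sum of incident bond orders, aromatic bonds counting 1.5."""
    if not (0 <= index < mol.n_atoms):
        raise IndexError(f"atom index {index} out of range")
    total = 0.0
    for b in mol.bonds:
        if index in (b.i, b.j):
            total += AROMATIC_ORDER if b.aromatic else float(b.order)
    return total


def prune_ligand(mol: MoleculeGraph, max_atoms: int = MAX_ATOMS) -> MoleculeGraph:
    """Iteratively drop the least-bonded atom until ``max_atoms`` remain.

    The total bond order is recomputed after every removal; ties go to the
    lowest original atom index, so the operation is deterministic. Atoms
    keep their relative order. Molecules already within the limit are
    returned unchanged.
    """
    if mol.n_atoms == 0:
        raise ValueError("cannot prune an empty molecule")
    if mol.n_atoms <= max_atoms:
        return mol
    # work on original indices; removal never renumbers until the end
    alive = list(range(mol.n_atoms))
    bonds = list(mol.bonds)
    while len(alive) > max_atoms:
        orders = {i: 0.0 for i in alive}
        for b in bonds:
            w = AROMATIC_ORDER if b.aromatic else float(b.order)
            orders[b.i] += w
            orders[b.j] += w
        victim = min(alive, key=lambda i: (orders[i], i))
        alive.remove(victim)
        bonds = [b for b in bonds if victim not in (b.i, b.j)]
    remap = {old: new for new, old in enumerate(alive)}
    return MoleculeGraph(
        [mol.elements[i] for i in alive],
        [Bond(remap[b.i], remap[b.j], b.order, b.aromatic) for b in bonds],
    )


@dataclass
class LigandGraph:
    """Fixed-size one-hot tensors for a <=36 heavy-atom molecule."""

    atom_types: np.ndarray  # (36, 7) uint8
    adjacency: np.ndarray   # (36, 36, 5) uint8
    n_atoms: int

    def __post_init__(self) -> None:
        self.atom_types = np.asarray(self.atom_types, dtype=np.uint8)
        self.adjacency = np.asarray(self.adjacency, dtype=np.uint8)
        if self.atom_types.shape != (MAX_ATOMS, 7):
            raise ValueError("atom_types must be 36x7")
        if self.adjacency.shape != (MAX_ATOMS, MAX_ATOMS, 5):
            raise ValueError("adjacency must be 36x36x5")

    def flatten(self, dtype=np.float32) -> np.ndarray:
        """Flat 6732-vector (atom types then adjacency, C order)."""
        return np.concatenate(
            [self.atom_types.astype(dtype).reshape(-1),
             self.adjacency.astype(dtype).reshape(-1)]
        )

    def validate(self) -> None:
        if self.atom_types.sum(axis=1).max() != 1 or \
                self.atom_types.sum(axis=1).min() != 1:
            raise ValueError("atom rows must be one-hot")
        if (self.atom_types[self.n_atoms:, 0] != 1).any():
            raise ValueError("padding rows must use the no-atom channel")
        if (self.adjacency.sum(axis=2) != 1).any():
            raise ValueError("adjacency cells must be one-hot")
        for c in range(5):
            if not np.array_equal(self.adjacency[..., c],
                                  self.adjacency[..., c].T):
                raise ValueError("adjacency must be symmetric per channel")
        diag = np.arange(MAX_ATOMS)
        if (self.adjacency[diag, diag, 1:] != 0).any():
            raise ValueError("diagonal must be no-bond")
        pad = self.adjacency[self.n_atoms:, :, 1:]
        if pad.any() or self.adjacency[:, self.n_atoms:, 1:].any():
            raise ValueError("padding rows/cols must be no-bond")


def encode_ligand(mol: MoleculeGraph) -> LigandGraph:
    """Encode a pruned molecule as the fixed 36x7 + 36x36x5 tensors."""
    if mol.n_atoms == 0:
        raise ValueError("cannot encode an empty molecule")
    if mol.n_atoms > MAX_ATOMS:
        raise ValueError(
            f"{mol.n_atoms} heavy atoms exceed the {MAX_ATOMS}-atom limit; "
            "apply prune_ligand first"
        )
    atom_types = np.zeros((MAX_ATOMS, 7), dtype=np.uint8)
    atom_types[:, 0] = 1
    for i, el in enumerate(mol.elements):
        atom_types[i, 0] = 0
        atom_types[i, atom_channel(el)] = 1
    adjacency = np.zeros((MAX_ATOMS, MAX_ATOMS, 5), dtype=np.uint8)
    adjacency[..., 0] = 1
    for b in mol.bonds:
        c = bond_channel(b)
        for i, j in ((b.i, b.j), (b.j, b.i)):
            adjacency[i, j, 0] = 0
            adjacency[i, j, c] = 1
    return LigandGraph(atom_types, adjacency, mol.n_atoms)
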