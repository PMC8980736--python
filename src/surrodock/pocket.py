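"""Binding-pocket extraction and voxel encoding.

The protein pocket is the set of protein atoms inside a 20 Å cube centered
at the bound ligand (or at a user-supplied coordinate for apo structures).
It is discretised on a 10 x 10 x 10 grid of 2 Å voxels, each voxel carrying
an 8-channel occupancy vector over (no atom, C, O, N, S, P, H, other).
When several atoms fall in one voxel the channel-wise maximum of their
one-hot encodings is taken, so a voxel can light up several element
channels at once; channel 0 is set only for voxels containing no atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "StructureAtoms",
    "PocketGrid",
    "PdbFormatError",
    "EmptyStructureError",
    "read_structure",
    "pocket_center",
    "select_pocket_atoms",
    "element_channel",
    "voxelize",
    "POCKET_CHANNELS",
    "GRID_SHAPE",
]

#: channel order of the pocket grid; index 0 is "no atom"
POCKET_CHANNELS = ("", "C", "O", "N", "S", "P", "H", "other")
GRID_SHAPE = (10, 10, 10, 8)

_ELEMENT_TO_CHANNEL = {"C": 1, "O": 2, "N": 3, "S": 4, "P": 5, "H": 6}


class PdbFormatError(ValueError):
    """Raised when a PDB record cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a structure contains no atoms."""


@dataclass(frozen=True)
class Atom:
    """A single atom with its element, position and residue classification."""

    element: str
    coords: tuple[float, float, float]
    residue_class: str  # "protein" | "hetero" | "water"
    altloc: str = ""
    occupancy: float = 1.0
    residue_name: str = ""

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("atom has empty element symbol")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates {self.coords!r}")


@dataclass
class StructureAtoms:
    """A flat list of atoms from a coordinate file, with array views."""

    atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3), dtype=float)
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def subset(self, mask) -> "StructureAtoms":
        return StructureAtoms([a for a, keep in zip(self.atoms, mask) if keep])

    def translated(self, shift) -> "StructureAtoms":
        shift = np.asarray(shift, dtype=float)
        return StructureAtoms(
            [
                Atom(a.element, tuple(np.asarray(a.coords) + shift), a.residue_class,
                     a.altloc, a.occupancy, a.residue_name)
                for a in self.atoms
            ]
        )


def _residue_class(residue: gemmi.Residue) -> str:
    if residue.is_water():
        return "water"
    info = gemmi.find_tabulated_residue(residue.name)
    if info is not None and info.is_amino_acid():
        return "protein"
    return "hetero"


#: elements that occur in standard amino-acid residues
_PROTEIN_ELEMENTS = {"C", "N", "O", "S", "H", "D", "SE", "P"}


def _element_symbol(atom: gemmi.Atom, residue_class: str) -> str:
    el = atom.element.name.upper().strip()
    letters = "".join(ch for ch in atom.name if ch.isalpha()).upper()
    # a blank element column makes the parser guess from the name, which
    # reads protein CA/CB/... as metals; re-infer from the first letter
    if residue_class == "protein" and el not in _PROTEIN_ELEMENTS:
        el = ""
    if el and el != "X":
        return el
    if not letters:
        return ""
    if residue_class != "protein" and len(letters) >= 2 \
            and gemmi.Element(letters[:2]).is_metal:
        return letters[:2]
    return letters[0]


def read_structure(pdb_text: str) -> StructureAtoms:
    """Parse ATOM/HETATM records from PDB text.

    Alternate locations of the same atom are collapsed to the
    highest-occupancy record (ties keep the first). Raises
    :class:`PdbFormatError` on malformed records and
    :class:`EmptyStructureError` if no atoms are found.
    """
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise PdbFormatError(str(exc)) from exc

    out: list[Atom] = []
    if len(structure) == 0:
        raise EmptyStructureError("no atoms in structure")
    model = structure[0]
    for chain in model:
        for residue in chain:
            rclass = _residue_class(residue)
            # collapse altlocs per atom name: highest occupancy, ties first
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in residue:
                if atom.name not in best:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > best[atom.name].occ:
                    best[atom.name] = atom
            for name in order:
                atom = best[name]
                el = _element_symbol(atom, rclass)
                if not el:
                    raise PdbFormatError(
                        f"cannot determine element for atom {atom.name!r} "
                        f"in residue {residue.name} {residue.seqid.num}"
                    )
                pos = (atom.pos.x, atom.pos.y, atom.pos.z)
                if not np.all(np.isfinite(pos)):
                    raise PdbFormatError(
                        f"non-finite coordinates for atom {atom.name!r}"
                    )
                out.append(
                    Atom(el, pos, rclass, atom.altloc.strip("\x00 "),
                         atom.occ, residue.name)
                )
    if not out:
        raise EmptyStructureError("no atoms in structure")
    return StructureAtoms(out)


def pocket_center(ligand_atoms: StructureAtoms) -> np.ndarray:
    """Unweighted centroid of the ligand's heavy atoms (hydrogens ignored)."""
    heavy = [a for a in ligand_atoms if a.element != "H"]
    if not heavy:
        raise ValueError("no heavy atoms to center the pocket on")
    return np.mean([a.coords for a in heavy], axis=0)


def select_pocket_atoms(
    atoms: StructureAtoms,
    center,
    side: float = 20.0,
    include_hetero: bool = False,
) -> StructureAtoms:
    """Protein atoms inside the half-open cube [center-side/2, center+side/2).

    Waters and (by default) hetero atoms/cofactors are excluded; the
    half-open bound keeps atoms on the lower face and drops atoms exactly
    on the upper face, so voxel indices never overflow.
    """
    if side <= 0:
        raise ValueError("cube side must be positive")
    center = np.asarray(center, dtype=float)
    half = side / 2.0
    kept: list[Atom] = []
    for a in atoms:
        if a.residue_class == "water":
            continue
        if a.residue_class == "hetero" and not include_hetero:
            continue
        d = np.asarray(a.coords) - center
        if np.all(d >= -half) and np.all(d < half):
            kept.append(a)
    return StructureAtoms(kept)


def element_channel(element: str) -> int:
    """Grid channel for a normalized element symbol (C/O/N/S/P/H, else 7)."""
    el = element.upper().strip()
    if not el:
        raise ValueError("empty element symbol")
    return _ELEMENT_TO_CHANNEL.get(el, 7)


@dataclass
class PocketGrid:
    """10x10x10x8 one-hot occupancy grid of a 20 Å pocket cube."""

    occupancy: np.ndarray
    center: np.ndarray
    resolution: float = 2.0
    side: float = 20.0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=np.uint8)
        self.center = np.asarray(self.center, dtype=float)
        if self.occupancy.shape != GRID_SHAPE:
            raise ValueError(
                f"grid shape {self.occupancy.shape} != {GRID_SHAPE}"
            )

    @property
    def n_voxels_per_axis(self) -> int:
        return int(round(self.side / self.resolution))

    def flatten(self, dtype=np.float32) -> np.ndarray:
        """Flat 8000-vector in C order, the protein-subnetwork input."""
        return self.occupancy.astype(dtype).reshape(-1)

    def validate(self) -> None:
        occ = self.occupancy
        if not np.isin(occ, (0, 1)).all():
            raise ValueError("grid entries must be 0 or 1")
        has_atom = occ[..., 1:].any(axis=-1)
        if not np.array_equal(occ[..., 0] == 1, ~has_atom):
            raise ValueError("channel-0 complementarity violated")

    @classmethod
    def empty(cls, center) -> "PocketGrid":
        occ = np.zeros(GRID_SHAPE, dtype=np.uint8)
        occ[..., 0] = 1
        return cls(occ, center)


def voxelize(atoms: StructureAtoms, center) -> PocketGrid:
    """Scatter pocket atoms into the 8-channel occupancy grid.

    Voxel index per axis is ``floor((x - (center - 10)) / 2)``; atoms must
    already lie inside the cube (use :func:`select_pocket_atoms`), otherwise
    a ValueError flags the selection/voxelization mismatch.
    """
    center = np.asarray(center, dtype=float)
    grid = np.zeros(GRID_SHAPE, dtype=np.uint8)
    if len(atoms):
        coords = atoms.coords
        idx = np.floor((coords - (center - 10.0)) / 2.0).astype(int)
        if (idx < 0).any() or (idx > 9).any():
            bad = np.where(((idx < 0) | (idx > 9)).any(axis=1))[0][0]
            raise ValueError(
                f"atom {bad} at {tuple(coords[bad])} lies outside the pocket "
                "cube; apply select_pocket_atoms first"
            )
        for (ix, iy, iz), el in zip(idx, atoms.elements):
            grid[ix, iy, iz, element_channel(el)] = 1
    empty = ~grid[..., 1:].any(axis=-1)
    grid[..., 0] = empty.astype(np.uint8)
    return PocketGrid(grid, center)
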