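"""Pocket extraction and voxel encoding."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from helpers import brute_force_voxelize, pdb_line
from surrodock import pocket as pk


class TestReadStructure:
    def test_single_atom_line(self):
        text = pdb_line(1, "CA", "ALA", "A", 1, 1.0, 2.0, 3.0,
                        element="C") + "\n"
        atoms = pk.read_structure(text)
        assert len(atoms) == 1
        assert atoms.atoms[0].element == "C"
        assert atoms.atoms[0].residue_class == "protein"
        np.testing.assert_allclose(atoms.atoms[0].coords, (1.0, 2.0, 3.0))

    def test_altloc_keeps_highest_occupancy(self, simple_pdb_text):
        atoms = pk.read_structure(simple_pdb_text)
        cb = [a for a in atoms if a.residue_name == "ALA"
              and abs(a.coords[1] + 1.4) < 0.05]
        assert len(cb) == 1
        assert cb[0].occupancy == pytest.approx(0.6)

    def test_altloc_tie_keeps_first(self):
        text = "\n".join([
            pdb_line(1, "CB", "ALA", "A", 1, 1.0, 0.0, 0.0, occ=0.5,
                     element="C", altloc="A"),
            pdb_line(2, "CB", "ALA", "A", 1, 2.0, 0.0, 0.0, occ=0.5,
                     element="C", altloc="B"),
        ]) + "\n"
        atoms = pk.read_structure(text)
        assert len(atoms) == 1
        assert atoms.atoms[0].coords[0] == pytest.approx(1.0)

    def test_residue_classes(self, simple_pdb_text):
        atoms = pk.read_structure(simple_pdb_text)
        classes = {a.residue_name: a.residue_class for a in atoms}
        assert classes["ALA"] == "protein"
        assert classes["HOH"] == "water"
        assert classes["LIG"] == "hetero"
        assert classes["ZN"] == "hetero"

    def test_water_only_file_gives_zero_pocket_atoms(self):
        text = pdb_line(1, "O", "HOH", "A", 1, 0.0, 0.0, 0.0,
                        element="O", record="HETATM") + "\n"
        atoms = pk.read_structure(text)
        assert len(pk.select_pocket_atoms(atoms, (0, 0, 0))) == 0

    def test_empty_structure_raises(self):
        with pytest.raises(pk.EmptyStructureError):
            pk.read_structure("END\n")

    def test_element_inferred_from_name_when_column_blank(self):
        text = pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0,
                        element="") + "\n"
        atoms = pk.read_structure(text)
        assert atoms.atoms[0].element == "C"


class TestPocketCenter:
    def test_single_atom(self):
        atoms = pk.StructureAtoms([pk.Atom("C", (1, 2, 3), "hetero")])
        np.testing.assert_allclose(pk.pocket_center(atoms), (1, 2, 3))

    def test_midpoint(self):
        atoms = pk.StructureAtoms([pk.Atom("C", (0, 0, 0), "hetero"),
                                   pk.Atom("O", (2, 0, 0), "hetero")])
        np.testing.assert_allclose(pk.pocket_center(atoms), (1, 0, 0))

    def test_symmetric_ring_centers_at_origin(self):
        ring = [(np.cos(t), np.sin(t), 0.0)
                for t in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
        atoms = pk.StructureAtoms([pk.Atom("C", xyz, "hetero")
                                   for xyz in ring])
        np.testing.assert_allclose(pk.pocket_center(atoms), (0, 0, 0),
                                   atol=1e-12)

    def test_hydrogens_ignored_and_heavy_required(self):
        atoms = pk.StructureAtoms([pk.Atom("H", (9, 9, 9), "hetero"),
                                   pk.Atom("C", (1, 1, 1), "hetero")])
        np.testing.assert_allclose(pk.pocket_center(atoms), (1, 1, 1))
        with pytest.raises(ValueError):
            pk.pocket_center(pk.StructureAtoms(
                [pk.Atom("H", (0, 0, 0), "hetero")]))


class TestSelectPocketAtoms:
    @pytest.mark.parametrize("offset,expected", [
        ((0.0, 0.0, 0.0), True),       # at center
        ((10.1, 0.0, 0.0), False),     # beyond half-width
        ((9.9, 9.9, 9.9), True),       # inside on all axes
        ((-9.9, -9.9, -9.9), True),
        ((10.0, 0.0, 0.0), False),     # exactly on the upper face
        ((-10.0, 0.0, 0.0), True),     # lower face is included (half-open)
    ])
    def test_half_open_cube(self, offset, expected):
        center = np.array([5.0, -3.0, 2.0])
        atoms = pk.StructureAtoms(
            [pk.Atom("C", tuple(center + offset), "protein")])
        kept = pk.select_pocket_atoms(atoms, center)
        assert (len(kept) == 1) is expected

    def test_nonprotein_excluded_by_default(self, simple_pdb_text):
        atoms = pk.read_structure(simple_pdb_text)
        kept = pk.select_pocket_atoms(atoms, (0.0, 0.0, 0.0))
        assert all(a.residue_class == "protein" for a in kept)
        # distant GLY CA at (30,30,30) is outside the cube
        assert len(kept) == 6
        hetero_too = pk.select_pocket_atoms(atoms, (0.0, 0.0, 0.0),
                                            include_hetero=True)
        assert len(hetero_too) == 9  # + ligand C, N and the zinc


class TestElementChannel:
    @pytest.mark.parametrize("element,channel", [
        ("C", 1), ("O", 2), ("N", 3), ("S", 4), ("P", 5), ("H", 6),
        ("FE", 7), ("ZN", 7), ("c", 1),
    ])
    def test_channel_order(self, element, channel):
        assert pk.element_channel(element) == channel

    def test_empty_symbol_rejected(self):
        with pytest.raises(ValueError):
            pk.element_channel("")


class TestVoxelize:
    def test_empty_grid_is_all_no_atom(self):
        grid = pk.voxelize(pk.StructureAtoms([]), (0, 0, 0))
        assert grid.occupancy.shape == (10, 10, 10, 8)
        assert (grid.occupancy[..., 0] == 1).all()
        assert (grid.occupancy[..., 1:] == 0).all()
        grid.validate()

    def test_atom_at_center_lands_in_central_voxel(self):
        atoms = pk.StructureAtoms([pk.Atom("C", (0.0, 0.0, 0.0), "protein")])
        grid = pk.voxelize(atoms, (0, 0, 0))
        assert grid.occupancy[5, 5, 5, 1] == 1
        assert grid.occupancy[5, 5, 5, 0] == 0
        assert grid.occupancy.sum() == 1 + 999  # one C + 999 empties

    def test_cohabiting_atoms_take_channelwise_maximum(self):
        atoms = pk.StructureAtoms([
            pk.Atom("C", (0.1, 0.1, 0.1), "protein"),
            pk.Atom("O", (0.3, 0.2, 0.1), "protein"),
        ])
        grid = pk.voxelize(atoms, (0, 0, 0))
        vox = grid.occupancy[5, 5, 5]
        assert vox[1] == 1 and vox[2] == 1 and vox[0] == 0

    def test_atom_outside_cube_raises(self):
        atoms = pk.StructureAtoms([pk.Atom("C", (11.0, 0.0, 0.0),
                                           "protein")])
        with pytest.raises(ValueError, match="outside"):
            pk.voxelize(atoms, (0, 0, 0))

    def test_ten_voxels_per_axis(self):
        grid = pk.PocketGrid.empty((0, 0, 0))
        assert grid.n_voxels_per_axis == 10
        assert grid.side / grid.resolution == 10

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_scatter(self, seed):
        from surrodock.synthetic import make_pocket
        atoms = make_pocket(seed, n_atoms=int(seed % 20) + 1)
        grid = pk.voxelize(atoms, (0.0, 0.0, 0.0))
        ref = brute_force_voxelize(
            [(a.coords, a.element) for a in atoms],
            (0.0, 0.0, 0.0), pk.element_channel)
        np.testing.assert_array_equal(grid.occupancy, np.array(ref))

    @given(st.integers(0, 10_000),
           st.tuples(*[st.floats(-50, 50) for _ in range(3)]))
    def test_translation_equivariance(self, seed, shift):
        from surrodock.synthetic import make_pocket
        atoms = make_pocket(seed, n_atoms=25)
        base = pk.voxelize(atoms, (0.0, 0.0, 0.0))
        moved = pk.voxelize(atoms.translated(shift), np.asarray(shift))
        np.testing.assert_array_equal(base.occupancy, moved.occupancy)

    @given(st.integers(0, 10_000))
    def test_grid_invariants_on_random_pockets(self, seed):
        from surrodock.synthetic import make_pocket
        grid = pk.voxelize(make_pocket(seed), (0.0, 0.0, 0.0))
        grid.validate()  # binary entries + channel-0 complementarity
        assert grid.flatten().shape == (8000,)
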