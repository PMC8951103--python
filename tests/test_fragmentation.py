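"""Fragmentation: scheme validation, cut-and-cap geometry, cap placement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragshare.complex_io import Atom, Molecule
from fragshare.fragmentation import (CAP_BOND_LENGTHS, CapPlacementError,
                                     FragmentDef, FragmentScheme, cut_and_cap,
                                     place_cap, validate_scheme)

from conftest import chain_molecule


def scheme_for_chain(n, split_after, cap_kind="hydrogen"):
    """Contiguous two-fragment scheme for an n-atom chain, cut after `split_after`."""
    return FragmentScheme(
        fragments=[
            FragmentDef("A", frozenset(range(1, split_after + 1))),
            FragmentDef("B", frozenset(range(split_after + 1, n + 1))),
        ],
        cut_bonds=[(split_after, split_after + 1)],
        cap_kind=cap_kind,
    )


class TestValidateScheme:
    def test_clean_partition_ok(self):
        report = validate_scheme(chain_molecule(10), scheme_for_chain(10, 6))
        assert report.ok and not report.messages

    def test_overlap_listed(self):
        scheme = FragmentScheme(
            fragments=[FragmentDef("A", frozenset(range(1, 8))),
                       FragmentDef("B", frozenset(range(7, 11)))],
            cut_bonds=[(6, 7)])
        report = validate_scheme(chain_molecule(10), scheme)
        assert not report.ok
        assert report.overlapping_atoms == [7]

    def test_missing_cut_bond_listed(self):
        scheme = FragmentScheme(
            fragments=[FragmentDef("A", frozenset(range(1, 7))),
                       FragmentDef("B", frozenset(range(7, 11)))],
            cut_bonds=[])
        report = validate_scheme(chain_molecule(10), scheme)
        assert not report.ok
        assert report.missing_cut_bonds == [(6, 7)]

    def test_coverage_gap_listed(self):
        scheme = FragmentScheme(
            fragments=[FragmentDef("A", frozenset(range(1, 6)))], cut_bonds=[])
        report = validate_scheme(chain_molecule(10), scheme)
        assert not report.ok
        assert report.missing_atoms == [6, 7, 8, 9, 10]

    def test_bogus_cut_bond_listed(self):
        scheme = FragmentScheme(
            fragments=[FragmentDef("A", frozenset(range(1, 7))),
                       FragmentDef("B", frozenset(range(7, 11)))],
            cut_bonds=[(6, 7), (1, 10)])
        report = validate_scheme(chain_molecule(10), scheme)
        assert (1, 10) in report.bogus_cut_bonds

    def test_ring_cut_warned_but_allowed(self):
        # 4-ring: 1-2-3-4-1
        atoms = [Atom(serial=i + 1, name=f"C{i+1}", element="C",
                      coords=np.array([[0, 0, 0], [1.5, 0, 0],
                                       [1.5, 1.5, 0], [0, 1.5, 0]][i], float))
                 for i in range(4)]
        ring = Molecule(atoms=atoms, bonds=[(0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 0, 1)])
        scheme = FragmentScheme(
            fragments=[FragmentDef("A", frozenset({1, 2})),
                       FragmentDef("B", frozenset({3, 4}))],
            cut_bonds=[(2, 3), (1, 4)])
        report = validate_scheme(ring, scheme)
        assert report.ok
        assert set(report.ring_bond_cuts) == {(2, 3), (1, 4)}


class TestCutAndCap:
    def test_ethane_split_gives_two_methane_like_fragments(self):
        mol = chain_molecule(2)
        frags = cut_and_cap(mol, scheme_for_chain(2, 1))
        assert [f.nh for f in frags] == [1, 1]
        for f, direction in zip(frags, (+1.0, -1.0)):
            assert f.n_caps == 1
            cap = f.molecule.atoms[f.cap_atom_indices[0]]
            assert cap.element == "H"
            stub = f.molecule.atoms[0]
            v = cap.coords - stub.coords
            assert np.linalg.norm(v) == pytest.approx(CAP_BOND_LENGTHS["C"], abs=1e-9)
            assert np.sign(v[0]) == direction  # along the former C-C vector

    def test_single_fragment_identity(self):
        mol = chain_molecule(5)
        scheme = FragmentScheme(
            fragments=[FragmentDef("ALL", frozenset(range(1, 6)))], cut_bonds=[])
        (frag,) = cut_and_cap(mol, scheme)
        assert frag.n_caps == 0
        assert frag.nh == mol.n_heavy
        np.testing.assert_array_equal(frag.molecule.coords, mol.coords)

    def test_middle_fragment_gets_two_caps(self):
        mol = chain_molecule(9)
        scheme = FragmentScheme(
            fragments=[FragmentDef("A", frozenset(range(1, 4))),
                       FragmentDef("B", frozenset(range(4, 7))),
                       FragmentDef("C", frozenset(range(7, 10)))],
            cut_bonds=[(3, 4), (6, 7)])
        frags = cut_and_cap(mol, scheme)
        assert [f.n_caps for f in frags] == [1, 2, 1]

    def test_original_coordinates_bit_identical(self):
        mol = chain_molecule(10)
        rng = np.random.default_rng(3)
        for a in mol.atoms:  # irrational-ish coordinates, not representable round
            a.coords = a.coords + rng.standard_normal(3) * 0.37
        frags = cut_and_cap(mol, scheme_for_chain(10, 4))
        for f in frags:
            for out_idx, serial in enumerate(f.original_atom_serials):
                orig = mol.atom_by_serial(serial).coords
                got = f.molecule.atoms[out_idx].coords
                assert np.array_equal(got, orig)  # exact, not approx

    def test_heavy_atom_union_equals_ligand(self):
        mol = chain_molecule(10)
        frags = cut_and_cap(mol, scheme_for_chain(10, 7))
        assert sum(f.nh for f in frags) == mol.n_heavy
        union = set()
        for f in frags:
            heavy = [s for i, s in enumerate(f.original_atom_serials)
                     if not f.molecule.atoms[i].is_hydrogen]
            union.update(heavy)
        assert union == {a.serial for a in mol.atoms}

    def test_deterministic(self):
        mol = chain_molecule(8)
        a = cut_and_cap(mol, scheme_for_chain(8, 3))
        b = cut_and_cap(mol, scheme_for_chain(8, 3))
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.molecule.coords, fb.molecule.coords)
            assert fa.molecule.bonds == fb.molecule.bonds

    def test_original_hydrogens_ride_along(self):
        mol = chain_molecule(2)
        h = Atom(serial=3, name="H1", element="H",
                 coords=np.array([0.0, 1.09, 0.0]), res_name="LIG", chain_id="L")
        mol = Molecule(atoms=mol.atoms + [h], bonds=mol.bonds + [(0, 2, 1)])
        frags = cut_and_cap(mol, scheme_for_chain(2, 1))
        names_a = {a.name for a in frags[0].molecule.atoms}
        assert "H1" in names_a
        assert frags[0].nh == 1  # hydrogens never count toward NH

    def test_methyl_cap_adds_heavy_cap_but_not_nh(self):
        mol = chain_molecule(4)
        frags = cut_and_cap(mol, scheme_for_chain(4, 2, cap_kind="methyl"))
        for f in frags:
            assert f.nh == 2
            caps = [f.molecule.atoms[i] for i in f.cap_atom_indices]
            assert [c.element for c in caps] == ["C", "H", "H", "H"]

    def test_cap_collision_is_typed_error(self):
        # bent chain with an atom sitting exactly where the cap would land
        atoms = [
            Atom(serial=1, name="C1", element="C", coords=np.array([0.0, 0, 0])),
            Atom(serial=2, name="C2", element="C", coords=np.array([1.54, 0, 0])),
            Atom(serial=3, name="C3", element="C", coords=np.array([1.09, 0.05, 0.0])),
        ]
        mol = Molecule(atoms=atoms, bonds=[(0, 1, 1), (0, 2, 1)])
        scheme = FragmentScheme(
            fragments=[FragmentDef("A", frozenset({1, 3})),
                       FragmentDef("B", frozenset({2}))],
            cut_bonds=[(1, 2)])
        with pytest.raises(CapPlacementError, match="clash"):
            cut_and_cap(mol, scheme)


class TestPlaceCap:
    def test_cap_along_former_bond_vector(self):
        stub = Atom(serial=1, name="C1", element="C", coords=np.zeros(3))
        (cap,) = place_cap(stub, np.array([1.54, 0.0, 0.0]))
        np.testing.assert_allclose(cap.coords, [CAP_BOND_LENGTHS["C"], 0, 0],
                                   atol=1e-12)

    def test_direction_preserved_on_z(self):
        stub = Atom(serial=1, name="O1", element="O", coords=np.zeros(3))
        (cap,) = place_cap(stub, np.array([0.0, 0.0, 2.0]))
        np.testing.assert_allclose(cap.coords, [0, 0, CAP_BOND_LENGTHS["O"]],
                                   atol=1e-12)

    def test_zero_length_direction_raises(self):
        stub = Atom(serial=1, name="C1", element="C", coords=np.ones(3))
        with pytest.raises(CapPlacementError):
            place_cap(stub, np.ones(3))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.tuples(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)).filter(
        lambda v: np.linalg.norm(v) > 1e-3))
    def test_cap_length_exact_for_random_directions(self, direction):
        stub = Atom(serial=1, name="N1", element="N",
                    coords=np.array([0.3, -0.2, 1.1]))
        departed = stub.coords + np.array(direction)
        (cap,) = place_cap(stub, departed)
        assert np.linalg.norm(cap.coords - stub.coords) == pytest.approx(
            CAP_BOND_LENGTHS["N"], abs=1e-6)

    def test_methyl_cap_geometry(self):
        stub = Atom(serial=1, name="C1", element="C", coords=np.zeros(3))
        caps = place_cap(stub, np.array([1.54, 0, 0]), cap_kind="methyl")
        c, hs = caps[0], caps[1:]
        assert np.linalg.norm(c.coords) == pytest.approx(1.54, abs=1e-9)
        for h in hs:
            assert np.linalg.norm(h.coords - c.coords) == pytest.approx(1.09, abs=1e-9)
            # tetrahedral angle with the stub->C axis
            v1 = -c.coords / np.linalg.norm(c.coords)
            v2 = h.coords - c.coords
            cosang = np.dot(v1, v2 / np.linalg.norm(v2))
            assert np.degrees(np.arccos(cosang)) == pytest.approx(109.471, abs=0.01)
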