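"""Structure I/O, interface residues and rigid superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ppiscreen import synthkit
from ppiscreen.structio import (
    Atom,
    Structure,
    interface_residues,
    read_structure,
    superpose,
    write_structure,
)

PDB_2ATOMS = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       2.500  -1.250   0.125  1.00  0.00           C
END
"""


def _mkatom(serial, chain, resnum, xyz, name="CA", element="C"):
    return Atom(serial, element, name, chain, resnum, "", "GLY", tuple(map(float, xyz)))


class TestReadWrite:
    def test_two_atom_pdb_coordinates_exact(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(PDB_2ATOMS)
        s = read_structure(p)
        assert len(s.atoms) == 2
        assert s.atoms[0].xyz == (1.0, 2.0, 3.0)
        assert s.atoms[1].xyz == (2.5, -1.25, 0.125)
        assert s.atoms[0].chain == "A" and s.atoms[0].resname == "ALA"

    def test_round_trip_identical_atom_table(self, tmp_path):
        s, _ = synthkit.make_random_dimer(n_per_chain=8, seed=2)
        p1 = tmp_path / "a.pdb"
        write_structure(s, p1)
        s2 = read_structure(p1)
        assert len(s2.atoms) == len(s.atoms)
        for a, b in zip(s.atoms, s2.atoms):
            assert (a.chain, a.resnum, a.name, a.resname) == (b.chain, b.resnum, b.name, b.resname)
            assert a.xyz == pytest.approx(b.xyz, abs=1e-3)
        p2 = tmp_path / "b.pdb"
        write_structure(s2, p2)
        assert p1.read_text() == p2.read_text()

    def test_multi_model_pose_file(self, tmp_path):
        _, coords, _, _ = synthkit.make_pose_ensemble([2, 1], jitter=0.5, seed=9)
        models = [
            [_mkatom(i + 1, "P", i + 1, c) for i, c in enumerate(pose)] for pose in coords
        ]
        p = tmp_path / "poses.pdb"
        write_structure(Structure(models=models), p)
        s = read_structure(p)
        assert len(s.models) == 3
        assert all(len(m) == coords.shape[1] for m in s.models)

    def test_unreadable_file_raises(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("not a structure\n")
        with pytest.raises(ValueError):
            read_structure(p)


class TestInterfaceResidues:
    def _pair(self, d):
        atoms = [_mkatom(1, "A", 1, (0, 0, 0)), _mkatom(2, "B", 1, (d, 0, 0))]
        return Structure(models=[atoms])

    def test_within_cutoff_both_reported(self):
        iface = interface_residues(self._pair(4.0), ["A"], ["B"], cutoff=5.0)
        assert iface.residuesA == {("A", 1)}
        assert iface.residuesB == {("B", 1)}

    def test_beyond_cutoff_empty(self):
        iface = interface_residues(self._pair(6.0), ["A"], ["B"], cutoff=5.0)
        assert not iface.residuesA and not iface.residuesB and not iface.contact_pairs

    def test_matches_brute_force_scan(self):
        s, _ = synthkit.make_random_dimer(n_per_chain=20, seed=1)
        iface = interface_residues(s, ["A"], ["B"], cutoff=5.0)
        expectA, expectB = set(), set()
        atomsA = [a for a in s.atoms if a.chain == "A"]
        atomsB = [a for a in s.atoms if a.chain == "B"]
        for a in atomsA:
            for b in atomsB:
                d = np.linalg.norm(np.subtract(a.xyz, b.xyz))
                if d <= 5.0:
                    expectA.add((a.chain, a.resnum))
                    expectB.add((b.chain, b.resnum))
        assert iface.residuesA == expectA
        assert iface.residuesB == expectB

    def test_symmetric_under_group_swap(self):
        s, _ = synthkit.make_random_dimer(n_per_chain=15, seed=4)
        ab = interface_residues(s, ["A"], ["B"], cutoff=5.0)
        ba = interface_residues(s, ["B"], ["A"], cutoff=5.0)
        assert ab.residuesA == ba.residuesB and ab.residuesB == ba.residuesA

    def test_monotone_in_cutoff(self):
        s, _ = synthkit.make_random_dimer(n_per_chain=15, seed=7)
        sizes = [
            len(interface_residues(s, ["A"], ["B"], cutoff=c).all_residues)
            for c in (3.0, 5.0, 8.0)
        ]
        assert sizes == sorted(sizes)

    def test_missing_chain_lists_available(self):
        s, _ = synthkit.make_random_dimer(n_per_chain=3, seed=1)
        with pytest.raises(ValueError, match="available"):
            interface_residues(s, ["A"], ["Z"], cutoff=5.0)


class TestSuperpose:
    def test_self_superposition_identity(self, rng):
        P = rng.normal(size=(20, 3))
        sup = superpose(P, P)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
        assert sup.n_atoms == 20

    def test_pure_translation_rmsd_zero(self, rng):
        P = rng.normal(size=(10, 3))
        sup = superpose(P, P + [10.0, 0.0, 0.0])
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_least_squares_oracle(self):
        rng = np.random.default_rng(7)
        P = rng.normal(size=(50, 3)) * 5.0
        R_true = Rotation.random(random_state=7).as_matrix()
        Q = P @ R_true.T + rng.normal(0, 0.1, size=(50, 3)) + [1.0, -2.0, 0.5]
        sup = superpose(P, Q)
        # independent closed-form oracle: scipy's Kabsch via align_vectors on
        # centered coordinates
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        rot, rssd = Rotation.align_vectors(Qc, Pc)
        oracle_rmsd = rssd / np.sqrt(len(P))
        assert sup.rmsd == pytest.approx(oracle_rmsd, abs=1e-9)
        assert np.allclose(sup.rotation, rot.as_matrix(), atol=1e-6)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_invariant_under_rigid_pretransform(self, rng):
        P = rng.normal(size=(30, 3))
        Q = rng.normal(size=(30, 3))
        base = superpose(P, Q).rmsd
        R = Rotation.random(random_state=3).as_matrix()
        moved = P @ R.T + [5.0, 5.0, -2.0]
        assert superpose(moved, Q).rmsd == pytest.approx(base, abs=1e-9)

    def test_transformed_coordinates_land_on_reference(self, rng):
        P = rng.normal(size=(12, 3))
        R = Rotation.random(random_state=11).as_matrix()
        Q = P @ R.T + [3.0, 1.0, -4.0]
        sup = superpose(P, Q)
        assert np.allclose(sup.apply(P), Q, atol=1e-9)

    @pytest.mark.parametrize(
        "pts",
        [
            np.array([[0.0, 0, 0], [1, 0, 0]]),  # too few
            np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),  # collinear
        ],
    )
    def test_degenerate_inputs_raise(self, pts):
        with pytest.raises(ValueError):
            superpose(pts, pts + 1.0)
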