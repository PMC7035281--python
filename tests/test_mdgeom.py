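"""Gate distances, dihedrals, substrate COM and ion coordination."""

import math

import numpy as np
import pytest

from conftest import build_frame, random_rotation
from leutkit.mdgeom import (GateDefinition, MissingAtomError, chi1,
                            classify_chi1, dihedral, gate_distances,
                            ion_coordination, substrate_com)


def gate_frame(extra=()):
    """Minimal frame holding both gate atom sets with a planted 4.00 A
    salt-bridge minimum and 3.00 A hydrogen-bond minimum."""
    atoms = [
        ("A", 5, "ARG", "NE", "protein", (0.0, 0.0, 10.0)),
        ("A", 5, "ARG", "NH1", "protein", (0.0, 0.0, 4.0)),
        ("A", 5, "ARG", "NH2", "protein", (0.0, 3.0, 10.0)),
        ("A", 369, "ASP", "OD1", "protein", (0.0, 0.0, 0.0)),
        ("A", 369, "ASP", "OD2", "protein", (0.0, 8.0, 0.0)),
        ("A", 268, "TYR", "OH", "protein", (20.0, 0.0, 0.0)),
        ("A", 361, "GLN", "OE1", "protein", (20.0, 3.0, 0.0)),
        ("A", 361, "GLN", "NE2", "protein", (20.0, -5.0, 0.0)),
    ]
    return build_frame(list(atoms) + list(extra))


class TestGateDistances:
    def test_planted_minimum_distances(self):
        d1, d2 = gate_distances(gate_frame())
        assert d1 == pytest.approx(4.00)
        assert d2 == pytest.approx(3.00)

    def test_missing_atom_error_names_the_atom(self):
        frame = gate_frame()
        frame = frame.subset(frame.atom_name != "OH")
        with pytest.raises(MissingAtomError, match="268"):
            gate_distances(frame)

    def test_matches_brute_force_minimum_over_random_frames(self, rng):
        gates = GateDefinition()
        for _ in range(50):
            atoms = []
            coords = {}
            for resid, names in ((5, gates.salt_bridge_a[1]),
                                 (369, gates.salt_bridge_b[1]),
                                 (268, gates.hbond_a[1]),
                                 (361, gates.hbond_b[1])):
                for nm in names:
                    xyz = tuple(rng.uniform(-20, 20, 3))
                    atoms.append(("A", resid, "XXX", nm, "protein", xyz))
                    coords[(resid, nm)] = xyz
            frame = build_frame(atoms)
            d1, d2 = gate_distances(frame, gates)
            brute1 = min(math.dist(coords[(5, a)], coords[(369, b)])
                         for a in gates.salt_bridge_a[1]
                         for b in gates.salt_bridge_b[1])
            brute2 = min(math.dist(coords[(268, a)], coords[(361, b)])
                         for a in gates.hbond_a[1]
                         for b in gates.hbond_b[1])
            assert d1 == pytest.approx(brute1, abs=1e-9)
            assert d2 == pytest.approx(brute2, abs=1e-9)


def chi1_frame(cg_xyz):
    atoms = [
        ("A", 268, "TYR", "N", "protein", (1.0, 1.0, 0.0)),
        ("A", 268, "TYR", "CA", "protein", (0.0, 0.0, 0.0)),
        ("A", 268, "TYR", "CB", "protein", (0.0, 0.0, 1.5)),
        ("A", 268, "TYR", "CG", "protein", cg_xyz),
    ]
    return build_frame(atoms)


class TestChi1:
    def test_anti_geometry_gives_180(self):
        # CG anti-periplanar to N across the CA-CB bond
        frame = chi1_frame((-1.0, -1.0, 1.5))
        assert abs(chi1(frame, 268)) == pytest.approx(180.0, abs=1e-9)
        assert classify_chi1(chi1(frame, 268)) == "out"

    def test_gauche_minus_constructed_analytically(self):
        """CG rotated -60 degrees from the N eclipsing position around the
        CA->CB axis (z), built from the rotation matrix directly."""
        # a -60 degree dihedral is a clockwise rotation of CG viewed along
        # CA->CB (+z), i.e. a +60 degree mathematical rotation about z
        ang = math.radians(60.0)
        # eclipsed (chi1=0) direction is the projection of CA->N onto the
        # plane normal to the CA->CB bond, here (1, 1, 0)/sqrt2
        ecl = np.array([1.0, 1.0, 0.0]) / math.sqrt(2)
        rot = np.array([[math.cos(ang), -math.sin(ang), 0.0],
                        [math.sin(ang), math.cos(ang), 0.0],
                        [0.0, 0.0, 1.0]])
        cg = tuple(rot @ ecl + np.array([0.0, 0.0, 1.5]))
        frame = chi1_frame(cg)
        assert chi1(frame, 268) == pytest.approx(-60.0, abs=1e-6)
        assert classify_chi1(chi1(frame, 268)) == "in"

    def test_mirror_image_negates_chi1(self, rng):
        frame = chi1_frame((-0.7, 0.9, 2.2))
        mirror = frame.transformed(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
        assert chi1(mirror, 268) == pytest.approx(-chi1(frame, 268), abs=1e-9)

    def test_missing_cg_raises_named_error(self):
        frame = chi1_frame((1.0, 0.0, 2.0))
        frame = frame.subset(frame.atom_name != "CG")
        with pytest.raises(MissingAtomError, match="CG"):
            chi1(frame, 268)


class TestSubstrateCom:
    def test_equal_masses_average_positions(self):
        frame = build_frame([
            ("S", 1, "LIG", "C1", "substrate", (0.0, 0.0, 0.0)),
            ("S", 1, "LIG", "C2", "substrate", (2.0, 0.0, 0.0))])
        np.testing.assert_allclose(substrate_com(frame), [1.0, 0.0, 0.0])

    def test_single_atom(self):
        frame = build_frame([
            ("S", 1, "LIG", "C1", "substrate", (3.0, -1.0, 2.0))])
        np.testing.assert_allclose(substrate_com(frame), [3.0, -1.0, 2.0])

    def test_mass_weighted_mean_matches_direct_sum(self):
        # phenylalanine-like heavy-atom composition: N, 2xO, 9xC
        atoms = [("S", 1, "PHE", "N", "substrate", (0.0, 0.0, 0.0)),
                 ("S", 1, "PHE", "O", "substrate", (1.0, 0.0, 0.0)),
                 ("S", 1, "PHE", "OXT", "substrate", (0.0, 1.0, 0.0))]
        atoms += [("S", 1, "PHE", f"C{k}", "substrate",
                   (float(k), 0.5, -0.5)) for k in range(9)]
        frame = build_frame(atoms)
        masses = {"N": 14.007, "O": 15.999, "C": 12.011}
        num = np.zeros(3)
        den = 0.0
        for a in atoms:
            m = masses[a[3][0]]
            num += m * np.array(a[5])
            den += m
        np.testing.assert_allclose(substrate_com(frame), num / den, atol=1e-9)

    def test_no_substrate_raises(self):
        with pytest.raises(ValueError, match="substrate"):
            substrate_com(chi1_frame((1.0, 0.0, 2.0)))


def octahedron(r=2.3):
    return [(r, 0, 0), (-r, 0, 0), (0, r, 0), (0, -r, 0), (0, 0, r),
            (0, 0, -r)]


class TestCoordination:
    def ion_frame(self, ligand_xyz):
        atoms = [("A", 500, "NA", "NA", "ion", (0.0, 0.0, 0.0))]
        for k, xyz in enumerate(ligand_xyz):
            atoms.append(("A", k + 1, "THR", "OG1", "protein", xyz))
        return build_frame(atoms)

    def test_six_ligands_labelled_octahedral(self):
        rep = ion_coordination(self.ion_frame(octahedron()), 500)
        assert rep.count == 6
        assert rep.geometry == "octahedral-like"

    def test_five_ligands_labelled_trigonal_bipyramidal(self):
        rep = ion_coordination(self.ion_frame(octahedron()[:5]), 500)
        assert rep.count == 5
        assert rep.geometry == "trigonal-bipyramidal-like"

    def test_shell_matches_brute_force_cutoff_scan(self, rng):
        xyz = [tuple(p) for p in rng.uniform(-5, 5, size=(40, 3))]
        frame = self.ion_frame(xyz)
        rep = ion_coordination(frame, 500, cutoff=3.0)
        brute = sorted(k + 1 for k, p in enumerate(xyz)
                       if math.dist(p, (0, 0, 0)) <= 3.0)
        assert sorted(e.resid for e in rep.entries) == brute
        dists = [e.distance for e in rep.entries]
        assert dists == sorted(dists)

    def test_unknown_ion_raises(self):
        with pytest.raises(KeyError, match="999"):
            ion_coordination(self.ion_frame(octahedron()), 999)


class TestDihedralConvention:
    def test_sign_convention_right_handed(self):
        # +90 degree dihedral for a right-handed twist
        p0, p1, p2 = (1.0, 0.0, 0.0), (0.0, 0.0, 0.0), (0.0, 0.0, 1.0)
        assert dihedral(p0, p1, p2, (0.0, -1.0, 1.0)) == pytest.approx(90.0)
        assert dihedral(p0, p1, p2, (0.0, 1.0, 1.0)) == pytest.approx(-90.0)

    def test_range_is_half_open_at_minus_180(self):
        p0, p1, p2 = (1.0, 0.0, 0.0), (0.0, 0.0, 0.0), (0.0, 0.0, 1.0)
        assert dihedral(p0, p1, p2, (-1.0, 0.0, 1.0)) == pytest.approx(180.0)
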