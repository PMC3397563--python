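import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lobedyn.errors import AtomLookupError, DegenerateFitError, PairingError
from lobedyn.geometry import (
    atom_distance,
    dihedral,
    kabsch,
    min_distance_to_group,
    omega_dihedrals,
    omega_for_residue,
    radius_of_gyration,
    superpose,
)
from lobedyn.structure_io import Atom, AtomSelection, Residue, Structure
from lobedyn.synthetic_data import ca_only_structure
from tests.conftest import random_rotation

CA = AtomSelection(atom_names=frozenset({"CA"}))


def grid_min_rmsd(mobile, reference, step_deg=10):
    """Brute-force oracle: best RMSD over a 10° Euler-angle rotation grid
    with the optimal (centroid) translation at each grid point."""
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)
    best = np.inf
    angles = np.radians(np.arange(0, 360, step_deg))
    betas = np.radians(np.arange(0, 181, step_deg))
    for a, b, c in itertools.product(angles, betas, angles):
        ca_, sa = np.cos(a), np.sin(a)
        cb, sb = np.cos(b), np.sin(b)
        cc, sc = np.cos(c), np.sin(c)
        rz1 = np.array([[ca_, -sa, 0], [sa, ca_, 0], [0, 0, 1]])
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
        r = rz1 @ ry @ rz2
        best = min(best, np.sqrt(np.mean(np.sum((p @ r.T - q) ** 2, axis=1))))
    return best


class TestSuperpose:
    def test_self_superposition(self, toy):
        res = superpose(toy, toy, CA)
        assert res.fit_rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(res.displacement_vectors, 0.0, atol=1e-10)

    def test_known_rotation_recovery(self):
        rng = np.random.default_rng(42)
        r0 = random_rotation(rng)
        t0 = np.array([1.0, -2.0, 3.0])
        cloud = rng.normal(scale=5.0, size=(10, 3))
        mobile = ca_only_structure(cloud, "mob")
        reference = ca_only_structure(cloud @ r0.T + t0, "ref")
        res = superpose(mobile, reference, CA)
        assert res.fit_rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(res.rotation, r0, atol=1e-8)

    def test_rotation_is_proper_orthonormal(self, toy, soft_toy):
        res = superpose(
            ca_only_structure(np.random.default_rng(0).normal(size=(8, 3))),
            ca_only_structure(np.random.default_rng(9).normal(size=(8, 3))),
            CA,
        )
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3),
                                   atol=1e-10)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_beats_grid_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(3):
            a = rng.normal(scale=4.0, size=(8, 3))
            b = rng.normal(scale=4.0, size=(8, 3))
            res = superpose(ca_only_structure(a), ca_only_structure(b), CA)
            assert res.fit_rmsd <= grid_min_rmsd(a, b) + 1e-9

    def test_rmsd_symmetric(self):
        rng = np.random.default_rng(3)
        a = ca_only_structure(rng.normal(scale=4.0, size=(12, 3)), "a")
        b = ca_only_structure(rng.normal(scale=4.0, size=(12, 3)), "b")
        fwd = superpose(a, b, CA).fit_rmsd
        rev = superpose(b, a, CA).fit_rmsd
        assert fwd == pytest.approx(rev, abs=1e-8)

    def test_too_few_atoms(self):
        a = ca_only_structure(np.array([[0.0, 0, 0], [1, 0, 0]]))
        with pytest.raises(DegenerateFitError):
            superpose(a, a.copy(), CA)

    def test_collinear_set(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        a = ca_only_structure(line)
        with pytest.raises(DegenerateFitError, match="collinear"):
            superpose(a, a.copy(), CA)

    def test_unpairable_selection(self, toy):
        shifted = toy.copy()
        for res in shifted.residues:
            res.number += 1000
        with pytest.raises(PairingError):
            superpose(toy, shifted, CA)

    def test_displacement_vectors_reference_frame(self):
        rng = np.random.default_rng(5)
        base = rng.normal(scale=4.0, size=(6, 3))
        shift = np.zeros_like(base)
        shift[0] = [0.5, 0.0, 0.0]
        mobile = ca_only_structure(base + shift, "m")
        reference = ca_only_structure(base, "r")
        sel = AtomSelection(residue_ranges=[("A", 2, 6)],
                            atom_names=frozenset({"CA"}))
        res = superpose(mobile, reference, fit_sel=sel, report_sel=CA)
        # fit residues 2..6 are identical, so the transform is near-identity
        # and residue 1 carries (reference − mobile) ≈ −shift
        np.testing.assert_allclose(res.displacement_vectors[0], -shift[0],
                                   atol=1e-8)

    def test_kabsch_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((4, 2)), np.zeros((4, 2)))


class TestRadiusOfGyration:
    def test_single_atom(self):
        s = ca_only_structure(np.array([[1.0, 2.0, 3.0]]))
        assert radius_of_gyration(s) == pytest.approx(0.0)

    def test_two_equal_masses(self):
        d = 6.0
        s = ca_only_structure(np.array([[0.0, 0, 0], [d, 0, 0]]))
        assert radius_of_gyration(s) == pytest.approx(d / 2)

    def test_mass_weighting(self):
        # C (12.011) at origin, O (15.999) at x=1: com at mO/(mC+mO)
        s = Structure(id="co")
        r = Residue("A", 1, name="XXX")
        r.atoms.append(Atom(serial=1, name="C", element="C",
                            coords=np.zeros(3)))
        r.atoms.append(Atom(serial=2, name="O", element="O",
                            coords=np.array([1.0, 0, 0])))
        s.residues.append(r)
        mc, mo = 12.011, 15.999
        com = mo / (mc + mo)
        expected = np.sqrt((mc * com ** 2 + mo * (1 - com) ** 2) / (mc + mo))
        assert radius_of_gyration(s) == pytest.approx(expected, rel=1e-12)

    def test_rigid_invariance(self, toy):
        rng = np.random.default_rng(11)
        r0 = random_rotation(rng)
        moved = toy.copy()
        for res in moved.residues:
            for atom in res.atoms:
                atom.coords = r0 @ atom.coords + np.array([3.0, -1.0, 8.0])
        assert radius_of_gyration(moved) == pytest.approx(
            radius_of_gyration(toy), abs=1e-10)

    def test_linear_scaling(self, toy):
        scaled = toy.copy()
        for res in scaled.residues:
            for atom in res.atoms:
                atom.coords = atom.coords * 2.5
        assert radius_of_gyration(scaled) == pytest.approx(
            2.5 * radius_of_gyration(toy), rel=1e-12)

    def test_empty_structure(self):
        with pytest.raises(ValueError):
            radius_of_gyration(Structure(id="empty"))


class TestDistances:
    def test_atom_to_itself(self, toy):
        assert atom_distance(toy, ("A", 1, "CA"), ("A", 1, "CA")) == 0.0

    def test_missing_atom_names_spec(self, toy):
        with pytest.raises(AtomLookupError, match="999"):
            atom_distance(toy, ("A", 1, "CA"), ("A", 999, "CA"))

    def test_min_distance_constructed(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]])
        s = ca_only_structure(coords)
        group = AtomSelection(residue_ranges=[("A", 2, 4)],
                              atom_names=frozenset({"CA"}))
        d, closest = min_distance_to_group(s, ("A", 1, "CA"), group)
        assert d == pytest.approx(1.0)
        assert closest.residue.number == 3

    def test_min_distance_zero_on_duplicate(self):
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0], [5.0, 0, 0]])
        s = ca_only_structure(coords)
        group = AtomSelection(residue_ranges=[("A", 2, 3)],
                              atom_names=frozenset({"CA"}))
        d, _ = min_distance_to_group(s, ("A", 1, "CA"), group)
        assert d == 0.0


def _peptide_pair(omega_deg):
    """Two residues whose linking ω torsion is exactly ``omega_deg``."""
    theta = np.radians(omega_deg)
    ca0 = np.array([-1.0, 1.0, 0.0])
    c0 = np.array([-1.0, 0.0, 0.0])
    n1 = np.array([0.3, 0.0, 0.0])
    ca1 = n1 + np.array([0.0, np.cos(theta), -np.sin(theta)])
    s = Structure(id="pep")
    r0 = Residue("A", 1, name="GLY")
    r0.atoms += [
        Atom(serial=1, name="CA", element="C", coords=ca0),
        Atom(serial=2, name="C", element="C", coords=c0),
    ]
    r1 = Residue("A", 2, name="GLY")
    r1.atoms += [
        Atom(serial=3, name="N", element="N", coords=n1),
        Atom(serial=4, name="CA", element="C", coords=ca1),
    ]
    s.residues += [r0, r1]
    return s


class TestOmega:
    def test_ideal_trans_peptide(self):
        s = _peptide_pair(180.0)
        [(key, ang)] = omega_dihedrals(s)
        assert key == ("A", 2, "")
        assert ang == pytest.approx(180.0, abs=1e-8)

    def test_constructed_90_degrees(self):
        [(_, ang)] = omega_dihedrals(_peptide_pair(90.0))
        assert ang == pytest.approx(90.0, abs=1e-8)

    def test_reported_in_0_360(self):
        [(_, ang)] = omega_dihedrals(_peptide_pair(192.1))
        assert ang == pytest.approx(192.1, abs=1e-8)

    def test_chain_break_skipped(self):
        s = _peptide_pair(180.0)
        for atom in s.residues[1].atoms:
            atom.coords = atom.coords + np.array([10.0, 0, 0])
        assert omega_dihedrals(s) == []

    def test_omega_for_residue_missing(self):
        with pytest.raises(AtomLookupError):
            omega_for_residue(_peptide_pair(180.0), "A", 99)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10 ** 6),
           st.floats(min_value=5.0, max_value=355.0))
    def test_rigid_invariance_and_mirror_negation(self, seed, omega):
        rng = np.random.default_rng(seed)
        s = _peptide_pair(omega)
        pts = [a.coords for _, a in s.iter_atoms()]
        r0 = random_rotation(rng)
        t0 = rng.normal(scale=10.0, size=3)
        moved = [r0 @ p + t0 for p in pts]
        mirrored = [p * np.array([1.0, 1.0, -1.0]) for p in pts]
        d_orig = dihedral(*pts)
        assert dihedral(*moved) == pytest.approx(d_orig, abs=1e-8)
        assert dihedral(*mirrored) % 360.0 == pytest.approx(
            (-d_orig) % 360.0, abs=1e-8)
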