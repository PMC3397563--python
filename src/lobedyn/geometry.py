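"""Rigid-body superposition, displacement fields and scalar geometric metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from lobedyn.errors import AtomLookupError, DegenerateFitError, PairingError
from lobedyn.structure_io import (
    Atom,
    AtomSelection,
    SelectedAtom,
    Structure,
    find_atom,
    resolve_selection,
)

logger = logging.getLogger(__name__)

# IUPAC 2021 standard atomic weights (abridged), keyed by element symbol.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904,
}

AtomSpec = Union[str, tuple]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform of *mobile* onto *reference* plus the
    displacement field over the reporting subset (reference frame)."""

    rotation: np.ndarray          # 3×3, det +1
    translation: np.ndarray       # 3-vector, Å
    fit_rmsd: float               # Å, over the fitting subset
    report_rmsd: float            # Å, over the reporting subset
    fit_pairs: list[tuple[SelectedAtom, SelectedAtom]]
    report_pairs: list[tuple[SelectedAtom, SelectedAtom]]
    displacement_vectors: np.ndarray  # n_report × 3, reference − transformed mobile

    @property
    def displacement_norms(self) -> np.ndarray:
        return np.linalg.norm(self.displacement_vectors, axis=1)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _atom_mass(atom: Atom) -> float:
    elem = atom.element.strip().upper()
    if not elem:
        name = atom.name.strip().upper().lstrip("0123456789")
        elem = name[:2] if name[:2] in ATOMIC_MASSES and len(name) > 1 else name[:1]
    try:
        return ATOMIC_MASSES[elem]
    except KeyError:
        raise AtomLookupError(f"no atomic mass for element {elem!r} (atom {atom.name})")


def pair_selections(
    a: Structure, b: Structure, sel: AtomSelection
) -> list[tuple[SelectedAtom, SelectedAtom]]:
    """Pair selected atoms across two structures by
    (chain, residue number, insertion code, atom name); intersection only —
    but raise if nothing pairs."""
    sel_a = resolve_selection(a, sel)
    sel_b = resolve_selection(b, sel)
    index_b = {(r.key, at.name): SelectedAtom(r, at) for r, at in sel_b}
    pairs = []
    for r, at in sel_a:
        match = index_b.get((r.key, at.name))
        if match is not None:
            pairs.append((SelectedAtom(r, at), match))
    if not pairs:
        missing = sorted({f"{r.chain_id}:{r.number}" for r, _ in sel_a})
        raise PairingError(f"no atoms pairable between {a.id!r} and {b.id!r}; "
                           f"selection covered {', '.join(missing[:20])}")
    return pairs


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares optimal proper rotation + translation taking ``mobile``
    onto ``reference`` (row-wise paired coordinates)."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("paired n×3 coordinate arrays required")
    if len(mobile) < 3:
        raise DegenerateFitError(f"need ≥3 paired atoms, got {len(mobile)}")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    p = mobile - cm
    q = reference - cr
    sv = np.linalg.svd(p, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateFitError("fitting subset is collinear")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    return rot, trans


def _rmsd(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


def superpose(
    mobile: Structure,
    reference: Structure,
    fit_sel: AtomSelection,
    report_sel: Optional[AtomSelection] = None,
) -> SuperpositionResult:
    """Superpose ``mobile`` onto ``reference`` over ``fit_sel`` and report
    displacement vectors over ``report_sel`` (defaults to the fit subset)."""
    fit_pairs = pair_selections(mobile, reference, fit_sel)
    report_pairs = (
        fit_pairs if report_sel is None else pair_selections(mobile, reference, report_sel)
    )
    mob_fit = np.array([p[0].atom.coords for p in fit_pairs])
    ref_fit = np.array([p[1].atom.coords for p in fit_pairs])
    rot, trans = kabsch(mob_fit, ref_fit)

    mob_rep = np.array([p[0].atom.coords for p in report_pairs])
    ref_rep = np.array([p[1].atom.coords for p in report_pairs])
    moved_rep = mob_rep @ rot.T + trans
    disp = ref_rep - moved_rep
    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        fit_rmsd=_rmsd(mob_fit @ rot.T + trans, ref_fit),
        report_rmsd=_rmsd(moved_rep, ref_rep),
        fit_pairs=fit_pairs,
        report_pairs=report_pairs,
        displacement_vectors=disp,
    )


def radius_of_gyration(s: Structure) -> float:
    """Mass-weighted radius of gyration, Å.  Expects a structure already
    passed through :func:`strip_for_geometry`."""
    coords, masses = [], []
    for _, atom in s.iter_atoms():
        coords.append(atom.coords)
        masses.append(_atom_mass(atom))
    if not coords:
        raise ValueError("empty structure")
    coords = np.array(coords)
    masses = np.array(masses)
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt((masses * sq).sum() / masses.sum()))


def _resolve_atom(s: Structure, spec: AtomSpec) -> Atom:
    if isinstance(spec, str):
        from lobedyn.structure_io import parse_atom_spec

        chain, number, name = parse_atom_spec(spec)
    else:
        chain, number, name = spec[0], spec[1], spec[2]
    return find_atom(s, chain, number, name)


def atom_distance(s: Structure, a: AtomSpec, b: AtomSpec) -> float:
    """Euclidean distance between two atoms (highest-occupancy conformers)."""
    pa = _resolve_atom(s, a)
    pb = _resolve_atom(s, b)
    return float(np.linalg.norm(pa.coords - pb.coords))


def min_distance_to_group(
    s: Structure, a: AtomSpec, group: AtomSelection
) -> tuple[float, SelectedAtom]:
    """Minimum distance from atom ``a`` to any atom of ``group``; ties broken
    by atom serial."""
    query = _resolve_atom(s, a)
    members = resolve_selection(s, group)
    best = min(
        members,
        key=lambda m: (float(np.linalg.norm(m.atom.coords - query.coords)), m.atom.serial),
    )
    return float(np.linalg.norm(best.atom.coords - query.coords)), best


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0–p1–p2–p3 in degrees, in (−180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def omega_dihedrals(
    s: Structure, max_peptide_bond: float = 2.5
) -> list[tuple[tuple[str, int, str], float]]:
    """ω torsion CA(i−1)–C(i−1)–N(i)–CA(i) per peptide bond, assigned to the
    C-terminal residue i and reported in [0°, 360°).  Chain breaks
    (C(i−1)–N(i) further than ``max_peptide_bond`` Å) are skipped and logged.
    """
    out: list[tuple[tuple[str, int, str], float]] = []
    for prev, cur in zip(s.residues, s.residues[1:]):
        if prev.chain_id != cur.chain_id:
            continue
        ca0, c0 = prev.get_atom("CA"), prev.get_atom("C")
        n1, ca1 = cur.get_atom("N"), cur.get_atom("CA")
        if None in (ca0, c0, n1, ca1):
            continue
        if np.linalg.norm(c0.coords - n1.coords) > max_peptide_bond:
            logger.info("chain break before %s:%s%s; omega skipped",
                        cur.chain_id, cur.number, cur.insertion_code)
            continue
        ang = dihedral(ca0.coords, c0.coords, n1.coords, ca1.coords) % 360.0
        out.append((cur.key, ang))
    return out


def omega_for_residue(s: Structure, chain: str, number: int, icode: str = "") -> float:
    """ω of the peptide bond into one residue; raises if absent."""
    for key, ang in omega_dihedrals(s):
        if key == (chain, number, icode):
            return ang
    raise AtomLookupError(f"no omega dihedral for residue {chain}:{number}{icode}")
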