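"""Hierarchical structure model and fixed-column PDB reading/writing.

Supports ATOM, HETATM, ANISOU, CRYST1, TER and MODEL/ENDMDL (first model
only).  ANISOU integers are converted to U tensors in Å² (×10⁻⁴) at parse
time and back on write, so a read→write→read round trip preserves them
exactly.
"""

from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np

from lobedyn.errors import AtomLookupError, EmptySelectionError, PDBParseError

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "TIP3"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Two-letter element symbols that commonly appear in PDB files; used to
# disambiguate the name-based hydrogen heuristic when the element column
# is blank (e.g. "HG" the atom name vs Hg the metal is settled by the
# record type upstream — heuristic only fires for blank element).
_TWO_LETTER_ELEMENTS = {
    "FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "SE", "CU", "NI", "CO",
    "CD", "HG", "PT", "AU", "AG", "PB", "LI", "AL", "SI",
}


@dataclass
class Atom:
    """One atom record; ``u_tensor`` holds the ANISOU tensor in Å²."""

    serial: int
    name: str
    altloc: str = ""
    element: str = ""
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    occupancy: float = 1.0
    b_iso: float = 0.0
    u_tensor: Optional[np.ndarray] = None
    is_hetero: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.u_tensor is not None:
            self.u_tensor = np.asarray(self.u_tensor, dtype=float)
            if not np.allclose(self.u_tensor, self.u_tensor.T):
                raise ValueError("u_tensor must be symmetric")

    @property
    def is_hydrogen(self) -> bool:
        elem = self.element.strip().upper()
        if elem:
            return elem in ("H", "D")
        # element column blank: fall back on the atom-name convention
        name = self.name.strip().upper().lstrip("0123456789")
        if not name:
            return False
        if name[:2] in _TWO_LETTER_ELEMENTS:
            return False
        return name[0] in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion_code: str = ""
    name: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.name.upper() in WATER_NAMES

    def atom_names(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.name not in seen:
                seen.append(a.name)
        return seen

    def conformers(self, name: str) -> list[Atom]:
        return [a for a in self.atoms if a.name == name]

    def get_atom(self, name: str, altloc: Optional[str] = None) -> Optional[Atom]:
        """Return atom by name; by default the highest-occupancy conformer
        (occupancy ties broken by altloc, 'A' before 'B')."""
        cands = self.conformers(name)
        if altloc is not None:
            cands = [a for a in cands if a.altloc == altloc]
        if not cands:
            return None
        return min(cands, key=lambda a: (-a.occupancy, a.altloc))


class UnitCell(NamedTuple):
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float


@dataclass
class Structure:
    id: str = ""
    residues: list[Residue] = field(default_factory=list)
    unit_cell: Optional[UnitCell] = None
    spacegroup: Optional[str] = None

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues:
            for atom in res.atoms:
                yield res, atom

    def residue_map(self) -> dict[tuple[str, int, str], Residue]:
        return {r.key: r for r in self.residues}

    def find_residue(self, chain: str, number: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.chain_id == chain and r.number == number and r.insertion_code == icode:
                return r
        return None

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    def n_atoms(self, heavy_only: bool = False) -> int:
        return sum(
            1 for _, a in self.iter_atoms() if not (heavy_only and a.is_hydrogen)
        )


class SelectedAtom(NamedTuple):
    residue: Residue
    atom: Atom


@dataclass
class AtomSelection:
    """Residue ranges (inclusive) × atom names × an altloc policy.

    ``residue_ranges=None`` selects all residues; ``atom_names=None`` all
    atom names.  Policies: ``highest_occupancy`` (one conformer per atom
    name), ``specific`` (only ``altloc``), ``all`` (every conformer).
    """

    residue_ranges: Optional[Sequence[tuple[str, int, int]]] = None
    atom_names: Optional[frozenset[str]] = None
    altloc_policy: str = "highest_occupancy"
    altloc: str = ""
    residue_names: Optional[frozenset[str]] = None

    def __post_init__(self):
        if self.altloc_policy not in ("highest_occupancy", "specific", "all"):
            raise ValueError(f"unknown altloc policy {self.altloc_policy!r}")
        if self.atom_names is not None:
            self.atom_names = frozenset(self.atom_names)
        if self.residue_names is not None:
            self.residue_names = frozenset(self.residue_names)

    def covers(self, res: Residue) -> bool:
        if self.residue_names is not None and res.name.upper() not in self.residue_names:
            return False
        if self.residue_ranges is None:
            return True
        return any(
            res.chain_id == chain and start <= res.number <= end
            for chain, start, end in self.residue_ranges
        )


def resolve_selection(s: Structure, sel: AtomSelection) -> list[SelectedAtom]:
    """Resolve ``sel`` against ``s`` into a deterministic ordered atom list.

    Atoms come back in structure order.  Raises
    :class:`EmptySelectionError` when nothing matches.
    """
    out: list[SelectedAtom] = []
    for res in s.residues:
        if not sel.covers(res):
            continue
        for name in res.atom_names():
            if sel.atom_names is not None and name not in sel.atom_names:
                continue
            if sel.altloc_policy == "all":
                out.extend(SelectedAtom(res, a) for a in res.conformers(name))
            elif sel.altloc_policy == "specific":
                atom = res.get_atom(name, altloc=sel.altloc)
                if atom is not None:
                    out.append(SelectedAtom(res, atom))
            else:
                atom = res.get_atom(name)
                if atom is not None:
                    out.append(SelectedAtom(res, atom))
    if not out:
        raise EmptySelectionError(f"selection matched no atoms in structure {s.id!r}")
    return out


def find_atom(s: Structure, chain: str, number: int, name: str,
              icode: str = "", altloc: Optional[str] = None) -> Atom:
    """Highest-occupancy conformer of one named atom, or raise."""
    res = s.find_residue(chain, number, icode)
    if res is None:
        raise AtomLookupError(f"residue {chain}:{number}{icode} not in {s.id!r}")
    atom = res.get_atom(name, altloc=altloc)
    if atom is None:
        raise AtomLookupError(f"atom {chain}:{number}{icode}:{name} not in {s.id!r}")
    return atom


def _is_polymer(res: Residue) -> bool:
    """Chain residue test used by strip_for_geometry: standard amino acids,
    or any residue (hetero or not) carrying a carbon CA atom — this keeps
    covalently linked nonstandard residues such as N-terminal pyroglutamate
    and excludes ions/solutes (a calcium ion's CA has element Ca)."""
    if res.is_water:
        return False
    if res.name.upper() in STANDARD_AA:
        return True
    if any(not a.is_hetero for a in res.atoms):
        return True
    ca = res.get_atom("CA")
    return ca is not None and ca.element.strip().upper() not in _TWO_LETTER_ELEMENTS


def strip_for_geometry(s: Structure) -> Structure:
    """Remove hydrogens, waters and non-polymer hetero groups, and collapse
    alternate conformers to the highest-occupancy one (occupancy reset to 1)."""
    out = Structure(id=s.id, unit_cell=s.unit_cell, spacegroup=s.spacegroup)
    for res in s.residues:
        if not _is_polymer(res):
            continue
        new_res = Residue(res.chain_id, res.number, res.insertion_code, res.name)
        for name in res.atom_names():
            atom = res.get_atom(name)
            if atom is None or atom.is_hydrogen:
                continue
            atom = _copy.deepcopy(atom)
            atom.altloc = ""
            atom.occupancy = 1.0
            new_res.atoms.append(atom)
        if new_res.atoms:
            out.residues.append(new_res)
    return out


# ---------------------------------------------------------------------------
# PDB parsing (v3.3 fixed columns)

def _parse_float(line: str, lo: int, hi: int, what: str, lineno: int,
                 default: Optional[float] = None) -> float:
    text = line[lo:hi].strip()
    if not text:
        if default is not None:
            return default
        raise PDBParseError(f"line {lineno}: missing {what} field")
    try:
        return float(text)
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad {what} field {text!r}") from exc


def _parse_int(line: str, lo: int, hi: int, what: str, lineno: int) -> int:
    text = line[lo:hi].strip()
    try:
        return int(text)
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad {what} field {text!r}") from exc


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str, str, int, str]:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: truncated ATOM/HETATM record")
    serial = _parse_int(line, 6, 11, "serial", lineno)
    name = line[12:16].strip()
    altloc = line[16:17].strip()
    resname = line[17:20].strip()
    chain = line[21:22].strip()
    resnum = _parse_int(line, 22, 26, "residue number", lineno)
    icode = line[26:27].strip()
    x = _parse_float(line, 30, 38, "x", lineno)
    y = _parse_float(line, 38, 46, "y", lineno)
    z = _parse_float(line, 46, 54, "z", lineno)
    occ = _parse_float(line, 54, 60, "occupancy", lineno, default=1.0)
    b = _parse_float(line, 60, 66, "B-factor", lineno, default=0.0)
    element = line[76:78].strip() if len(line) >= 78 else ""
    atom = Atom(
        serial=serial, name=name, altloc=altloc, element=element,
        coords=np.array([x, y, z]), occupancy=min(max(occ, 0.0), 1.0),
        b_iso=b, is_hetero=line.startswith("HETATM"),
    )
    return atom, resname, chain, resnum, icode


def _parse_anisou_line(line: str, lineno: int) -> tuple[int, np.ndarray]:
    if len(line) < 70:
        raise PDBParseError(f"line {lineno}: truncated ANISOU record")
    serial = _parse_int(line, 6, 11, "serial", lineno)
    ints = [
        _parse_int(line, 28 + 7 * k, 35 + 7 * k, f"U({k})", lineno) for k in range(6)
    ]
    u11, u22, u33, u12, u13, u23 = (v * 1.0e-4 for v in ints)
    u = np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])
    return serial, u


def read_pdb(path, structure_id: Optional[str] = None) -> Structure:
    """Parse a PDB-format file into a :class:`Structure` (first model only)."""
    path = str(path)
    s = Structure(id=structure_id or path.rsplit("/", 1)[-1].split(".")[0])
    current: Optional[Residue] = None
    by_serial: dict[int, Atom] = {}
    n_coord = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            rec = line[:6]
            if rec == "ENDMDL":
                break  # first model only
            if rec in ("ATOM  ", "HETATM"):
                atom, resname, chain, resnum, icode = _parse_atom_line(line, lineno)
                key = (chain, resnum, icode)
                if current is None or current.key != key or current.name != resname:
                    current = s.find_residue(chain, resnum, icode)
                    if current is None:
                        current = Residue(chain, resnum, icode, resname)
                        s.residues.append(current)
                current.atoms.append(atom)
                by_serial[atom.serial] = atom
                n_coord += 1
            elif rec == "ANISOU":
                serial, u = _parse_anisou_line(line, lineno)
                atom = by_serial.get(serial)
                if atom is None:
                    warnings.warn(
                        f"line {lineno}: ANISOU serial {serial} has no matching "
                        "ATOM record; dropped"
                    )
                    continue
                atom.u_tensor = u
            elif rec == "CRYST1":
                if len(line) < 54:
                    raise PDBParseError(f"line {lineno}: truncated CRYST1 record")
                s.unit_cell = UnitCell(
                    _parse_float(line, 6, 15, "a", lineno),
                    _parse_float(line, 15, 24, "b", lineno),
                    _parse_float(line, 24, 33, "c", lineno),
                    _parse_float(line, 33, 40, "alpha", lineno),
                    _parse_float(line, 40, 47, "beta", lineno),
                    _parse_float(line, 47, 54, "gamma", lineno),
                )
                sg = line[55:66].strip()
                s.spacegroup = sg or None
    if n_coord == 0:
        raise PDBParseError(f"{path}: no ATOM or HETATM records found")
    return s


# ---------------------------------------------------------------------------
# PDB writing

def _format_atom_name(atom: Atom) -> str:
    name = atom.name
    if len(name) >= 4:
        return name[:4]
    elem = atom.element.strip().upper()
    if len(elem) == 2 or (not elem and name[:2] in _TWO_LETTER_ELEMENTS):
        return f"{name:<4}"
    return f" {name:<3}"


def write_pdb(s: Structure, path) -> None:
    """Write ``s`` in fixed-column PDB format, including ANISOU records."""
    lines: list[str] = []
    if s.unit_cell is not None:
        a, b, c, al, be, ga = s.unit_cell
        sg = s.spacegroup or "P 1"
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} {sg:<11s}"
        )
    serial = 0
    for res, atom in s.iter_atoms():
        serial += 1
        rec = "HETATM" if atom.is_hetero else "ATOM  "
        x, y, z = atom.coords
        lines.append(
            f"{rec}{serial:5d} {_format_atom_name(atom)}{atom.altloc or ' ':1s}"
            f"{res.name:<3s} {res.chain_id or 'A':1s}{res.number:4d}"
            f"{res.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_iso:6.2f}"
            f"          {atom.element:>2s}"
        )
        if atom.u_tensor is not None:
            u = atom.u_tensor
            ints = [
                int(round(v * 1.0e4))
                for v in (u[0, 0], u[1, 1], u[2, 2], u[0, 1], u[0, 2], u[1, 2])
            ]
            lines.append(
                f"ANISOU{serial:5d} {_format_atom_name(atom)}"
                f"{atom.altloc or ' ':1s}{res.name:<3s} {res.chain_id or 'A':1s}"
                f"{res.number:4d}{res.insertion_code or ' ':1s} "
                + "".join(f"{v:7d}" for v in ints)
                + f"      {atom.element:>2s}"
            )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Text specs used by the CLI and pipeline configs

def parse_selection_spec(spec: str) -> AtomSelection:
    """Parse ``"A:55-58,86-91,96-101:CA"`` into an :class:`AtomSelection`.

    Fields are chain, comma-separated inclusive ranges (or ``all``), and
    comma-separated atom names (or ``*``); the last two are optional.
    """
    parts = spec.split(":")
    if not parts or not parts[0]:
        raise ValueError(f"bad selection spec {spec!r}")
    chain = parts[0]
    ranges: Optional[list[tuple[str, int, int]]] = None
    if len(parts) > 1 and parts[1] and parts[1].lower() != "all":
        ranges = []
        for chunk in parts[1].split(","):
            if "-" in chunk[1:]:  # allow negative start
                lo, hi = chunk.rsplit("-", 1)
                ranges.append((chain, int(lo), int(hi)))
            else:
                ranges.append((chain, int(chunk), int(chunk)))
    names: Optional[frozenset[str]] = None
    if len(parts) > 2 and parts[2] and parts[2] != "*":
        names = frozenset(n.strip().upper() for n in parts[2].split(","))
    return AtomSelection(residue_ranges=ranges, atom_names=names)


def parse_atom_spec(spec: str) -> tuple[str, int, str]:
    """Parse ``"A:35:N"`` into (chain, residue number, atom name)."""
    parts = spec.split(":")
    if len(parts) != 3:
        raise ValueError(f"bad atom spec {spec!r}; expected chain:resnum:name")
    return parts[0], int(parts[1]), parts[2].strip().upper()
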