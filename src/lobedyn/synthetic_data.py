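"""Deterministic generators for synthetic test structures.

The two-lobe toy places each lobe in an azimuthal wedge around a hinge
axis (z, through the neck apex at the origin).  Rotating lobe B about
that axis toward lobe A then *strictly* shrinks every inter-lobe
distance — for xy-projections a⊥, b⊥ at azimuths φa > φb + θ,
cos(φa − φb − θ) > cos(φa − φb) — which is what the difference-distance
sign tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from lobedyn.adp import b_eq
from lobedyn.anm import ModeShape
from lobedyn.structure_io import Atom, Residue, Structure


@dataclass
class ToyStructureSpec:
    """Parameters of the bi-lobed Cα toy.

    ``hinge_stiffness_ratio`` ∈ (0, 1] emulates a softer hinge by widening
    the azimuthal gap between the lobes (γ is uniform in the network model,
    so stiffness can only be shaped geometrically).
    """

    n_lobe_a: int = 12
    n_lobe_b: int = 12
    lobe_separation: float = 20.0
    hinge_stiffness_ratio: float = 1.0
    seed: int = 0
    n_neck: int = 5
    neck_height: float = 5.0
    z_spread: float = 2.5
    cutoff: float = 15.0

    def __post_init__(self):
        if self.n_lobe_a < 4 or self.n_lobe_b < 4:
            raise ValueError("each lobe needs at least 4 nodes")
        if not 0.0 < self.hinge_stiffness_ratio <= 1.0:
            raise ValueError("hinge_stiffness_ratio must be in (0, 1]")

    @property
    def half_gap_deg(self) -> float:
        # wedge centres move apart as the hinge is made softer
        return 25.0 + 15.0 * (1.0 - self.hinge_stiffness_ratio)


def soft_hinge_spec(seed: int = 0) -> ToyStructureSpec:
    """Toy parameters whose slowest nontrivial mode is the in-plane hinge
    closure: lobes coupled only through the neck (no direct contacts at the
    15 Å cutoff) and a wide azimuthal gap."""
    return ToyStructureSpec(
        seed=seed, hinge_stiffness_ratio=0.25, lobe_separation=34.0
    )


def ca_only_structure(coords: np.ndarray, structure_id: str = "synthetic") -> Structure:
    s = Structure(id=structure_id)
    for i, xyz in enumerate(coords, start=1):
        res = Residue(chain_id="A", number=i, name="ALA")
        res.atoms.append(
            Atom(serial=i, name="CA", element="C", coords=np.asarray(xyz, float),
                 occupancy=1.0, b_iso=10.0)
        )
        s.residues.append(res)
    return s


def _wedge_points(rng, n, az_lo, az_hi, r_lo, r_hi, z_spread):
    az = np.radians(rng.uniform(az_lo, az_hi, size=n))
    r = rng.uniform(r_lo, r_hi, size=n)
    z = rng.uniform(-z_spread, z_spread, size=n)
    return np.column_stack([r * np.cos(az), r * np.sin(az), z])


def _check_connected(coords: np.ndarray, cutoff: float) -> None:
    dist = squareform(pdist(coords))
    contact = (dist <= cutoff) & ~np.eye(len(coords), dtype=bool)
    n_comp, _ = connected_components(contact, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"toy parameters give a disconnected network at cutoff {cutoff} Å"
        )


def make_two_lobe(spec: ToyStructureSpec = ToyStructureSpec()) -> Structure:
    """Two compact Cα clusters bridged by a thin neck; CA-only ALA residues,
    chain A, numbered 1..N (lobe A, then neck, then lobe B), occupancy 1.
    Coordinates are pre-rounded to 3 decimals so PDB round trips are exact,
    and generation is byte-deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    half = spec.half_gap_deg
    r_mid = spec.lobe_separation / 2.0
    r_lo, r_hi = max(r_mid - 4.0, 6.0), r_mid + 4.0
    lobe_a = _wedge_points(rng, spec.n_lobe_a, half, half + 40.0, r_lo, r_hi,
                           spec.z_spread)
    # vertical column near the apex: stiffens out-of-plane bending and
    # torsion so the in-plane closure is the softest internal motion
    neck = np.column_stack([
        np.full(spec.n_neck, 4.0) + rng.uniform(-0.3, 0.3, size=spec.n_neck),
        rng.uniform(-0.3, 0.3, size=spec.n_neck),
        np.linspace(-spec.neck_height, spec.neck_height, spec.n_neck),
    ])
    lobe_b = _wedge_points(rng, spec.n_lobe_b, -half - 40.0, -half, r_lo, r_hi,
                           spec.z_spread)
    coords = np.round(np.vstack([lobe_a, neck, lobe_b]), 3)
    _check_connected(coords, spec.cutoff)
    return ca_only_structure(coords, f"two_lobe_seed{spec.seed}")


def two_lobe_blocks(spec: ToyStructureSpec) -> dict[str, list[tuple[str, int, int]]]:
    """Residue ranges of the generated lobes/neck, for selections and DDM
    block summaries."""
    na, nn, nb = spec.n_lobe_a, spec.n_neck, spec.n_lobe_b
    return {
        "lobe_a": [("A", 1, na)],
        "neck": [("A", na + 1, na + nn)],
        "lobe_b": [("A", na + nn + 1, na + nn + nb)],
    }


def make_hinge_closed(
    base: Structure, spec: ToyStructureSpec, angle_deg: float = 5.0
) -> Structure:
    """Rotate lobe B about the hinge (z) axis by ``angle_deg`` toward lobe A.

    Construction guarantees every inter-lobe Cα distance strictly decreases
    for 0 < angle < azimuthal gap; intra-lobe distances change only by the
    3-decimal coordinate rounding."""
    if not 0 < angle_deg < 2 * spec.half_gap_deg:
        raise ValueError("angle must be within the inter-lobe azimuthal gap")
    theta = np.radians(angle_deg)
    rot = np.array([
        [np.cos(theta), -np.sin(theta), 0.0],
        [np.sin(theta), np.cos(theta), 0.0],
        [0.0, 0.0, 1.0],
    ])
    first_b = spec.n_lobe_a + spec.n_neck + 1
    out = base.copy()
    out.id = f"{base.id}_closed{angle_deg:g}"
    for res in out.residues:
        if res.number >= first_b:
            for atom in res.atoms:
                atom.coords = np.round(rot @ atom.coords, 3)
    return out


def make_conformer_pair(
    base: Structure, mode: ModeShape, amplitude: float
) -> Structure:
    """Displace the toy's Cα coordinates by ``amplitude`` × the (oriented)
    mode vectors.  Coordinates are kept at full precision (no PDB rounding)
    so the displacement field reproduces the mode exactly."""
    n = sum(1 for _ in base.residues)
    if mode.per_node_vectors.shape != (n, 3):
        raise ValueError("mode node count does not match structure")
    out = base.copy()
    out.id = f"{base.id}_mode{mode.index}a{amplitude:g}"
    for res, vec in zip(out.residues, mode.per_node_vectors):
        for atom in res.atoms:
            atom.coords = atom.coords + amplitude * vec
    return out


def _orthonormal_basis(axis: np.ndarray) -> np.ndarray:
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(a @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    b = np.cross(a, helper)
    b /= np.linalg.norm(b)
    c = np.cross(a, b)
    return np.column_stack([a, b, c])


def make_synthetic_adps(
    s: Structure,
    axis_field: np.ndarray | None = None,
    ratio: float = 0.25,
    scale: float = 2.0,
    seed: int = 0,
) -> Structure:
    """Plant per-atom U tensors with anisotropy exactly ``ratio`` and largest
    principal axis along ``axis_field`` (random unit vectors when omitted).

    U = R·diag(scale, scale·g, scale·ratio)·Rᵀ with g ~ U[ratio, 1] per atom.
    The default scale keeps the ANISOU ×10⁴ integer rounding error on the
    recovered anisotropy below 1e-4.  b_iso is set to Bₑq (2 decimals)."""
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio must be in (0, 1]")
    if scale <= 0.0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    atoms = [atom for _, atom in s.iter_atoms()]
    if axis_field is None:
        axis_field = rng.normal(size=(len(atoms), 3))
    axis_field = np.asarray(axis_field, float)
    if axis_field.shape != (len(atoms), 3):
        raise ValueError("axis_field must provide one 3-vector per atom")
    out = s.copy()
    out.id = f"{s.id}_adps"
    for atom, axis in zip((a for _, a in out.iter_atoms()), axis_field):
        g = rng.uniform(ratio, 1.0)
        basis = _orthonormal_basis(axis)
        u = basis @ np.diag([scale, scale * g, scale * ratio]) @ basis.T
        u = 0.5 * (u + u.T)
        atom.u_tensor = u
        atom.b_iso = round(b_eq(u), 2)
    return out
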