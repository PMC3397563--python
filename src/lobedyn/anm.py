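"""Anisotropic network model (ANM) normal-mode analysis of a Cα network.

Uniform springs within a distance cutoff; dense symmetric eigensolver
(networks here are a few hundred nodes at most).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from lobedyn.errors import UndefinedOverlapError
from lobedyn.structure_io import AtomSelection, Structure, resolve_selection

logger = logging.getLogger(__name__)

TRIVIAL_TOL = 1e-8  # λ < tol·λ_max counts as a rigid-body (trivial) mode


@dataclass
class ANMModel:
    node_coords: np.ndarray            # N×3, Å
    gamma: float
    cutoff: float
    hessian: np.ndarray                # 3N×3N
    node_labels: list = field(default_factory=list)
    connected: bool = True
    eigenvalues: Optional[np.ndarray] = None   # ascending, full spectrum
    eigenvectors: Optional[np.ndarray] = None  # columns, orthonormal
    n_trivial: Optional[int] = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)


@dataclass
class ModeShape:
    """One normal mode: 1-based index over the full spectrum (the first
    nontrivial mode of a connected network is 7)."""

    index: int
    eigenvalue: float
    per_node_vectors: np.ndarray   # N×3; flattened vector has unit norm
    phase_sign: int = 1            # ±1 once phase-oriented
    phase_degenerate: bool = False

    @property
    def flat(self) -> np.ndarray:
        return self.per_node_vectors.ravel()

    @property
    def square_fluctuations(self) -> np.ndarray:
        return np.sum(self.per_node_vectors ** 2, axis=1) / self.eigenvalue


def build_hessian(
    coords: np.ndarray,
    gamma: float = 1.0,
    cutoff: float = 15.0,
    node_labels: Optional[list] = None,
) -> ANMModel:
    """Assemble the 3N×3N ANM Hessian.

    Off-diagonal 3×3 block for a contact pair (r ≤ cutoff):
    H_ij = −(γ/r²)·(r_ij ⊗ r_ij); diagonal blocks enforce zero block-row
    sums.  Duplicate coordinates within the cutoff are an error; a
    disconnected contact network is allowed but logged (n_trivial > 6).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) < 2:
        raise ValueError("need an N×3 coordinate array with N ≥ 2")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(coords)
    dist = squareform(pdist(coords))
    contact = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    if np.any(contact & (dist == 0.0)):
        i, j = np.argwhere(contact & (dist == 0.0))[0]
        raise ValueError(f"duplicate node coordinates (nodes {i} and {j})")

    diff = coords[:, None, :] - coords[None, :, :]       # N×N×3
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(contact, -gamma / np.where(dist > 0, dist, 1.0) ** 2, 0.0)
    blocks = k[:, :, None, None] * diff[:, :, :, None] * diff[:, :, None, :]
    diag = -blocks.sum(axis=1)
    blocks[np.arange(n), np.arange(n)] = diag
    hessian = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    hessian = 0.5 * (hessian + hessian.T)  # kill rounding asymmetry

    n_comp, _ = connected_components(contact, directed=False)
    if n_comp > 1:
        logger.warning(
            "contact network is disconnected (%d components) at cutoff %.2f Å; "
            "expect more than 6 near-zero modes", n_comp, cutoff,
        )
    return ANMModel(
        node_coords=coords,
        gamma=gamma,
        cutoff=cutoff,
        hessian=hessian,
        node_labels=node_labels or [],
        connected=n_comp == 1,
    )


def ca_model(
    s: Structure, gamma: float = 1.0, cutoff: float = 15.0
) -> ANMModel:
    """Build an ANM over the Cα atoms of a structure (highest-occupancy
    conformers; nonstandard chain residues with a CA are included)."""
    sel = AtomSelection(atom_names=frozenset({"CA"}))
    selected = [
        sa for sa in resolve_selection(s, sel)
        if sa.atom.element.strip().upper() in ("C", "")
    ]
    coords = np.array([sa.atom.coords for sa in selected])
    labels = [sa.residue.key for sa in selected]
    return build_hessian(coords, gamma=gamma, cutoff=cutoff, node_labels=labels)


def diagonalize(m: ANMModel, n_modes: int = 6) -> list[ModeShape]:
    """Full dense eigendecomposition; returns the ``n_modes`` slowest
    nontrivial modes, numbered from n_trivial+1 over the full spectrum."""
    vals, vecs = np.linalg.eigh(m.hessian)
    m.eigenvalues = vals
    m.eigenvectors = vecs
    lam_max = float(vals[-1])
    if lam_max <= 0:
        raise ValueError("Hessian has no positive eigenvalue")
    trivial = vals < TRIVIAL_TOL * lam_max
    m.n_trivial = int(trivial.sum())
    modes = []
    n = m.n_nodes
    for k in range(m.n_trivial, min(m.n_trivial + n_modes, 3 * n)):
        modes.append(
            ModeShape(
                index=k + 1,
                eigenvalue=float(vals[k]),
                per_node_vectors=vecs[:, k].reshape(n, 3).copy(),
            )
        )
    return modes


def mode_overlap(mode: ModeShape, displacements: np.ndarray) -> float:
    """Signed cosine overlap between a mode and a per-node displacement
    field (both flattened and unit-normalized)."""
    d = np.asarray(displacements, dtype=float).ravel()
    u = mode.flat
    if d.shape != u.shape:
        raise ValueError(
            f"displacement field has {d.size // 3} nodes, mode has {u.size // 3}"
        )
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise UndefinedOverlapError("zero displacement field")
    return float(u @ d / (np.linalg.norm(u) * nd))


def _rg_derivative(coords: np.ndarray, vectors: np.ndarray) -> float:
    # d/dε of Σ‖r_i + εv_i − com(ε)‖²; mean-velocity term vanishes because
    # Σ(r_i − com) = 0
    com = coords.mean(axis=0)
    return float(2.0 * np.sum((coords - com) * vectors))


def phase_orient(mode: ModeShape, coords: np.ndarray) -> ModeShape:
    """Orient a mode so that a small displacement along it decreases the
    radius of gyration (the compaction phase).  Idempotent; insensitive to
    the solver's arbitrary input sign.  A pure-twist mode (zero Rg
    derivative) falls back to the first-nonzero-component-positive
    convention and is flagged."""
    coords = np.asarray(coords, dtype=float)
    v = mode.per_node_vectors
    deriv = _rg_derivative(coords, v)
    scale = 2.0 * np.linalg.norm(coords - coords.mean(axis=0)) * np.linalg.norm(v)
    if abs(deriv) < 1e-10 * max(scale, 1.0):
        flat = v.ravel()
        nz = flat[np.abs(flat) > 1e-12]
        sign = 1 if (len(nz) == 0 or nz[0] > 0) else -1
        return replace(
            mode,
            per_node_vectors=sign * v,
            phase_sign=sign * mode.phase_sign,
            phase_degenerate=True,
        )
    sign = -1 if deriv > 0 else 1
    return replace(
        mode,
        per_node_vectors=sign * v,
        phase_sign=sign * mode.phase_sign,
        phase_degenerate=False,
    )


def square_fluctuation_profile(modes: list[ModeShape]) -> np.ndarray:
    """Per-node mean-square fluctuation summed over modes: Σ_k ‖u_k(i)‖²/λ_k."""
    return np.sum([m.square_fluctuations for m in modes], axis=0)


def write_nmd(
    m: ANMModel, modes: list[ModeShape], stream, name: str = "lobedyn"
) -> None:
    """Minimal NMD-style export consumable by normal-mode viewers."""
    stream.write(f"nmwiz_load {name}.nmd\n")
    stream.write(f"name {name}\n")
    coords = " ".join(f"{v:.3f}" for v in m.node_coords.ravel())
    stream.write(f"coordinates {coords}\n")
    if m.node_labels:
        stream.write(
            "resids " + " ".join(str(k[1]) for k in m.node_labels) + "\n"
        )
    for mode in modes:
        vec = " ".join(f"{v:.5f}" for v in mode.flat)
        stream.write(f"mode {mode.index} {mode.eigenvalue:.6g} {vec}\n")
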