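"""Anisotropic displacement parameter (ADP) analysis.

Equivalent isotropic B, tensor eigendecomposition, anisotropy
A = λ_min/λ_max, and outlier selection of the most anisotropic atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from lobedyn.errors import DegenerateTensorError
from lobedyn.structure_io import AtomSelection, SelectedAtom, Structure, resolve_selection

logger = logging.getLogger(__name__)

_EIGH_CLAMP = 1e-8  # deposited tensors can be marginally non-PSD after rounding

B_EQ_FACTOR = 8.0 * np.pi ** 2 / 3.0


def _check_symmetric(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.shape != (3, 3) or not np.allclose(u, u.T, atol=1e-10):
        raise ValueError("ADP tensor must be a symmetric 3×3 matrix")
    return u


def b_eq(u: np.ndarray) -> float:
    """Isotropic-equivalent B-factor (8π²/3)·trace(U), Å²."""
    return float(B_EQ_FACTOR * np.trace(_check_symmetric(u)))


def _eigen(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues descending (clamped to ≥0 near zero) + matching
    orthonormal eigenvectors as columns."""
    vals, vecs = np.linalg.eigh(_check_symmetric(u))
    vals = vals[::-1].copy()
    vecs = vecs[:, ::-1].copy()
    small = (vals > -_EIGH_CLAMP) & (vals <= 0)
    vals[small] = 0.0
    return vals, vecs


def anisotropy(u: np.ndarray) -> float:
    """λ_min/λ_max of the ADP tensor; 1 for an isotropic sphere."""
    vals, _ = _eigen(u)
    if vals[0] <= 0:
        raise DegenerateTensorError("largest eigenvalue is not positive")
    return float(vals[2] / vals[0])


@dataclass
class ADPRecord:
    """Per-atom ADP summary: tensor, Bₑq, eigensystem and anisotropy."""

    atom_ref: tuple[tuple[str, int, str], str]  # (residue key, atom name)
    u_tensor: np.ndarray
    b_eq: float
    eigenvalues: np.ndarray     # λ₁ ≥ λ₂ ≥ λ₃, Å²
    eigenvectors: np.ndarray    # columns match eigenvalues
    anisotropy: float

    @property
    def principal_axis(self) -> np.ndarray:
        """Largest principal axis scaled by its eigenvalue λ₁."""
        return self.eigenvectors[:, 0] * self.eigenvalues[0]


def make_record(residue_key, atom_name: str, u: np.ndarray) -> ADPRecord:
    vals, vecs = _eigen(u)
    if vals[0] <= 0:
        raise DegenerateTensorError(
            f"degenerate ADP tensor on {residue_key}:{atom_name}"
        )
    return ADPRecord(
        atom_ref=(residue_key, atom_name),
        u_tensor=np.asarray(u, dtype=float),
        b_eq=b_eq(u),
        eigenvalues=vals,
        eigenvectors=vecs,
        anisotropy=float(vals[2] / vals[0]),
    )


def adp_records(
    s: Structure,
    sel: AtomSelection = AtomSelection(atom_names=frozenset({"CA"})),
) -> list[ADPRecord]:
    """ADP records for the selected atoms that carry a U tensor; atoms
    without ANISOU are excluded (and logged), not treated as isotropic."""
    records = []
    skipped = 0
    for sa in resolve_selection(s, sel):
        if sa.atom.u_tensor is None:
            skipped += 1
            continue
        records.append(make_record(sa.residue.key, sa.atom.name, sa.atom.u_tensor))
    if skipped:
        logger.info("%d selected atoms lack ANISOU records; excluded", skipped)
    return records


def selection_threshold(mean: float, sd: float, k: float = 0.5) -> float:
    """Anisotropy cut-off mean − k·SD below which atoms count as strongly
    anisotropic."""
    return mean - k * sd


def select_anisotropic(
    records: list[ADPRecord], k: float = 0.5
) -> tuple[float, list[ADPRecord]]:
    """Atoms whose anisotropy lies below mean − k·SD (sample SD, strict
    inequality).  Returns (threshold, selected records)."""
    if len(records) < 2:
        raise ValueError("need ≥2 ADP records to form a distribution")
    a = np.array([r.anisotropy for r in records])
    threshold = selection_threshold(float(a.mean()), float(a.std(ddof=1)), k)
    return threshold, [r for r in records if r.anisotropy < threshold]


def anisotropy_stats(records: list[ADPRecord]) -> dict:
    a = np.array([r.anisotropy for r in records])
    b = np.array([r.b_eq for r in records])
    return {
        "n": len(records),
        "anisotropy_mean": float(a.mean()),
        "anisotropy_sd": float(a.std(ddof=1)) if len(records) > 1 else 0.0,
        "anisotropy_min": float(a.min()),
        "anisotropy_max": float(a.max()),
        "b_eq_mean": float(b.mean()),
        "b_eq_sd": float(b.std(ddof=1)) if len(records) > 1 else 0.0,
        "b_eq_min": float(b.min()),
        "b_eq_max": float(b.max()),
    }
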