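"""Difference distance matrices: superposition-free comparison of two
conformations over a paired residue selection."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, TextIO

import numpy as np
from scipy.spatial.distance import squareform, pdist

from lobedyn.errors import EmptySelectionError
from lobedyn.geometry import pair_selections
from lobedyn.structure_io import AtomSelection, Structure, resolve_selection

CA_SELECTION = AtomSelection(atom_names=frozenset({"CA"}))


@dataclass
class DifferenceDistanceMatrix:
    """Entry (i, j) is d_b(i, j) − d_a(i, j) over paired Cα (or other) atoms.

    Symmetric, zero diagonal, invariant under rigid motion of either input.
    """

    residue_labels: list[tuple[str, int]]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.residue_labels),) * 2:
            raise ValueError("matrix shape does not match label count")

    def summary(
        self,
        blocks: Optional[dict[str, Sequence[tuple[str, int, int]]]] = None,
    ) -> dict:
        """Off-diagonal statistics; with ``blocks`` (name → residue ranges),
        adds the mean over each inter-block pair of entries."""
        n = len(self.residue_labels)
        mask = ~np.eye(n, dtype=bool)
        off = self.values[mask]
        out = {
            "n_residues": n,
            "mean": float(off.mean()),
            "fraction_negative": float((off < 0).mean()),
            "min": float(off.min()),
            "max": float(off.max()),
        }
        if blocks:
            idx = {
                name: np.array([
                    i for i, (chain, num) in enumerate(self.residue_labels)
                    if any(c == chain and lo <= num <= hi for c, lo, hi in ranges)
                ], dtype=int)
                for name, ranges in blocks.items()
            }
            names = list(blocks)
            block_means = {}
            for i, na in enumerate(names):
                for nb in names[i:]:
                    ia, ib = idx[na], idx[nb]
                    if len(ia) == 0 or len(ib) == 0:
                        continue
                    sub = self.values[np.ix_(ia, ib)]
                    if na == nb:
                        m = ~np.eye(len(ia), dtype=bool)
                        if not m.any():
                            continue
                        block_means[f"{na}~{nb}"] = float(sub[m].mean())
                    else:
                        block_means[f"{na}~{nb}"] = float(sub.mean())
            out["block_means"] = block_means
        return out

    def save_heatmap(self, path) -> None:
        """Optional diverging heat map centred at 0 (red = closer, blue =
        apart); cosmetic companion to the TSV export."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vmax = max(float(np.abs(self.values).max()), 1e-6)
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.values, cmap="RdBu", vmin=-vmax, vmax=vmax,
                       origin="lower")
        ax.set_xlabel("residue index")
        ax.set_ylabel("residue index")
        fig.colorbar(im, ax=ax, label="Δ distance (Å)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    def to_tsv(self, stream: TextIO, precision: int = 4) -> None:
        labels = [f"{c}{n}" for c, n in self.residue_labels]
        stream.write("\t".join(["residue"] + labels) + "\n")
        for lab, row in zip(labels, self.values):
            stream.write(lab + "\t" + "\t".join(f"{v:.{precision}f}" for v in row) + "\n")


def distance_matrix(s: Structure, sel: AtomSelection = CA_SELECTION) -> np.ndarray:
    """Symmetric matrix of pairwise Euclidean distances over a selection."""
    selected = resolve_selection(s, sel)
    if len(selected) < 2:
        raise EmptySelectionError("distance matrix needs ≥2 selected atoms")
    coords = np.array([sa.atom.coords for sa in selected])
    return squareform(pdist(coords))


def difference_distance(
    a: Structure, b: Structure, sel: AtomSelection = CA_SELECTION
) -> DifferenceDistanceMatrix:
    """d_b − d_a over atoms pairable in both structures (intersection)."""
    pairs = pair_selections(a, b, sel)
    labels = [(pa.residue.chain_id, pa.residue.number) for pa, _ in pairs]
    ca = np.array([pa.atom.coords for pa, _ in pairs])
    cb = np.array([pb.atom.coords for _, pb in pairs])
    da = squareform(pdist(ca))
    db = squareform(pdist(cb))
    return DifferenceDistanceMatrix(residue_labels=labels, values=db - da)
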