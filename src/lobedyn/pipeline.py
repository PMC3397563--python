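"""End-to-end comparative report: superpositions, DDM, ADP statistics,
elastic-network modes and the scalar metrics, written as JSON + TSV tables."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from lobedyn import __version__
from lobedyn.adp import adp_records, anisotropy_stats, select_anisotropic
from lobedyn.anm import ModeShape, ca_model, diagonalize, mode_overlap, phase_orient
from lobedyn.ddm import difference_distance
from lobedyn.errors import StageError, UndefinedOverlapError
from lobedyn.geometry import atom_distance, radius_of_gyration, superpose
from lobedyn.structure_io import (
    AtomSelection,
    Structure,
    read_pdb,
    strip_for_geometry,
)

logger = logging.getLogger(__name__)

# Default named residue sets: the two β-sheets founding the lobes plus the
# two mobile lobe-2 segments used for block summaries.
DEFAULT_V1 = ((55, 58), (86, 91), (96, 101))
DEFAULT_V2 = ((11, 12), (33, 38), (63, 70), (77, 84))
DEFAULT_SEGMENT_I = ((13, 32),)
DEFAULT_SEGMENT_II = ((71, 75),)


@dataclass
class AnalysisConfig:
    reference: str = ""
    mobile: str = ""
    chain: str = "A"
    v1: tuple = DEFAULT_V1
    v2: tuple = DEFAULT_V2
    segment_i: tuple = DEFAULT_SEGMENT_I
    segment_ii: tuple = DEFAULT_SEGMENT_II
    cleft: tuple = ((35, "N"), (98, "N"))
    custom_distances: list = field(default_factory=list)
    anm_cutoff: float = 15.0
    anm_gamma: float = 1.0
    anm_modes: int = 6
    adp_k: float = 0.5
    outdir: str = "lobedyn_report"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def _ranges(self, pairs) -> list[tuple[str, int, int]]:
        return [(self.chain, int(lo), int(hi)) for lo, hi in pairs]

    def selection(self, which: str, atoms=frozenset({"CA"})) -> AtomSelection:
        ranges = {
            "v1": self.v1,
            "v2": self.v2,
            "segment_i": self.segment_i,
            "segment_ii": self.segment_ii,
        }[which]
        return AtomSelection(residue_ranges=self._ranges(ranges), atom_names=atoms)

    def blocks(self) -> dict:
        return {
            "V1": self._ranges(self.v1),
            "V2": self._ranges(self.v2),
            "segment_I": self._ranges(self.segment_i),
            "segment_II": self._ranges(self.segment_ii),
        }


GLOBAL_CA = AtomSelection(atom_names=frozenset({"CA"}))


def _fmt(x: float, nd: int) -> float:
    return float(round(float(x), nd))


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def _stage(report: dict, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def run_report(cfg: AnalysisConfig) -> dict:
    """Run the full comparison of ``cfg.mobile`` against ``cfg.reference``
    and write report.json plus TSV tables into ``cfg.outdir``.

    Partial outputs are retained on stage failure; errors carry the stage
    name."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": {"name": "lobedyn", "version": __version__},
        "config": asdict(cfg),
    }
    pkg_logger = logging.getLogger("lobedyn")
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    pkg_logger.addHandler(log_handler)
    if pkg_logger.level > logging.INFO or pkg_logger.level == logging.NOTSET:
        pkg_logger.setLevel(logging.INFO)
    logger.info("lobedyn %s; config: %s", __version__, asdict(cfg))

    def flush():
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")

    try:
        with _stage(report, "read"):
            ref = read_pdb(cfg.reference)
            mob = read_pdb(cfg.mobile)
            ref_geo = strip_for_geometry(ref)
            mob_geo = strip_for_geometry(mob)
            report["inputs"] = {
                "reference": {"id": ref.id, "n_heavy_atoms": ref.n_atoms(heavy_only=True)},
                "mobile": {"id": mob.id, "n_heavy_atoms": mob.n_atoms(heavy_only=True)},
            }

        with _stage(report, "superpose_global"):
            sup_global = superpose(mob_geo, ref_geo, GLOBAL_CA)
            report["superposition"] = {
                "global_ca_rmsd": _fmt(sup_global.fit_rmsd, 2),
                "n_pairs": len(sup_global.fit_pairs),
            }

        with _stage(report, "superpose_v1"):
            sup_v1 = superpose(mob_geo, ref_geo, cfg.selection("v1"), GLOBAL_CA)
            norms = sup_v1.displacement_norms
            report["superposition"]["v1_fit_rmsd"] = _fmt(sup_v1.fit_rmsd, 2)
            report["superposition"]["v1_report_rmsd"] = _fmt(sup_v1.report_rmsd, 2)
            report["superposition"]["v1_displacements"] = {
                "min": _fmt(norms.min(), 2),
                "max": _fmt(norms.max(), 2),
            }
            rows = [
                [sa_ref.residue.chain_id, sa_ref.residue.number,
                 f"{n:.3f}", f"{v[0]:.3f}", f"{v[1]:.3f}", f"{v[2]:.3f}"]
                for (sa_mob, sa_ref), n, v in zip(
                    sup_v1.report_pairs, norms, sup_v1.displacement_vectors)
            ]
            _write_tsv(outdir / "displacements_v1fit.tsv",
                       ["chain", "residue", "norm_A", "dx", "dy", "dz"], rows)

        with _stage(report, "ddm"):
            dd = difference_distance(mob_geo, ref_geo, GLOBAL_CA)
            with open(outdir / "ddm.tsv", "w") as fh:
                dd.to_tsv(fh)
            report["ddm"] = dd.summary(blocks=cfg.blocks())

        with _stage(report, "adp"):
            records = adp_records(ref, GLOBAL_CA)
            if len(records) >= 2:
                stats = anisotropy_stats(records)
                threshold, selected = select_anisotropic(records, k=cfg.adp_k)
                selected_keys = {r.atom_ref for r in selected}
                report["adp"] = {
                    "n_ca_with_anisou": stats["n"],
                    "b_eq_mean": _fmt(stats["b_eq_mean"], 1),
                    "b_eq_sd": _fmt(stats["b_eq_sd"], 1),
                    "b_eq_range": [_fmt(stats["b_eq_min"], 1), _fmt(stats["b_eq_max"], 1)],
                    "anisotropy_mean": _fmt(stats["anisotropy_mean"], 4),
                    "anisotropy_sd": _fmt(stats["anisotropy_sd"], 4),
                    "anisotropy_range": [
                        _fmt(stats["anisotropy_min"], 4), _fmt(stats["anisotropy_max"], 4)],
                    "selection_threshold": _fmt(threshold, 4),
                    "n_selected": len(selected),
                }
                rows = []
                for r in records:
                    (chain, num, icode), name = r.atom_ref
                    ax = r.principal_axis
                    rows.append([
                        chain, num, name, f"{r.b_eq:.2f}",
                        f"{r.eigenvalues[0]:.5f}", f"{r.eigenvalues[1]:.5f}",
                        f"{r.eigenvalues[2]:.5f}", f"{r.anisotropy:.4f}",
                        int(r.atom_ref in selected_keys),
                        f"{ax[0]:.5f}", f"{ax[1]:.5f}", f"{ax[2]:.5f}",
                    ])
                _write_tsv(outdir / "adp.tsv",
                           ["chain", "residue", "atom", "b_eq", "lam1", "lam2",
                            "lam3", "anisotropy", "selected", "ax_x", "ax_y", "ax_z"],
                           rows)
            else:
                report["adp"] = {"n_ca_with_anisou": len(records),
                                 "note": "too few ANISOU-bearing CA atoms"}

        with _stage(report, "anm"):
            model = ca_model(ref_geo, gamma=cfg.anm_gamma, cutoff=cfg.anm_cutoff)
            modes = diagonalize(model, n_modes=cfg.anm_modes)
            modes = [phase_orient(mode, model.node_coords) for mode in modes]
            disp_by_key = {
                sa_ref.residue.key: vec
                for (sa_mob, sa_ref), vec in zip(
                    sup_v1.report_pairs, sup_v1.displacement_vectors)
            }
            idx = [i for i, key in enumerate(model.node_labels) if key in disp_by_key]
            disp = np.array([disp_by_key[model.node_labels[i]] for i in idx])
            overlaps = []
            for mode in modes:
                entry = {"mode": mode.index, "eigenvalue": float(mode.eigenvalue)}
                try:
                    sub = ModeShape(
                        index=mode.index, eigenvalue=mode.eigenvalue,
                        per_node_vectors=mode.per_node_vectors[idx],
                    )
                    signed = mode_overlap(sub, disp)
                    entry["overlap_signed"] = _fmt(signed, 4)
                    entry["overlap_abs"] = _fmt(abs(signed), 4)
                except UndefinedOverlapError:
                    entry["overlap_signed"] = None
                    entry["overlap_abs"] = None
                    entry["note"] = "undefined (zero displacement field)"
                overlaps.append(entry)
            report["anm"] = {
                "n_nodes": model.n_nodes,
                "connected": model.connected,
                "n_trivial": model.n_trivial,
                "eigenvalues": [float(f"{m.eigenvalue:.6g}") for m in modes],
                "mode_overlap_v1fit_displacements": overlaps,
            }
            for mode in modes:
                rows = [
                    [key[0], key[1], f"{sf:.6g}",
                     f"{v[0]:.5f}", f"{v[1]:.5f}", f"{v[2]:.5f}"]
                    for key, sf, v in zip(
                        model.node_labels, mode.square_fluctuations,
                        mode.per_node_vectors)
                ]
                _write_tsv(outdir / f"anm_mode{mode.index}.tsv",
                           ["chain", "residue", "square_fluctuation",
                            "vx", "vy", "vz"], rows)
            from lobedyn.anm import write_nmd

            with open(outdir / "modes.nmd", "w") as fh:
                write_nmd(model, modes, fh, name=ref.id or "reference")

        with _stage(report, "metrics"):
            (r1, a1), (r2, a2) = cfg.cleft
            spec_a = (cfg.chain, int(r1), a1)
            spec_b = (cfg.chain, int(r2), a2)
            cleft = {}
            for label, s in (("reference", ref), ("mobile", mob)):
                try:
                    cleft[label] = _fmt(atom_distance(s, spec_a, spec_b), 2)
                except Exception:
                    cleft[label] = None
            custom = []
            for pair in cfg.custom_distances:
                sa, sb = pair
                custom.append({
                    "a": sa, "b": sb,
                    "reference": _fmt(atom_distance(ref, tuple(sa), tuple(sb)), 2),
                    "mobile": _fmt(atom_distance(mob, tuple(sa), tuple(sb)), 2),
                })
            report["metrics"] = {
                "cleft_width": cleft,
                "custom_distances": custom,
                "radius_of_gyration": {
                    "reference": _fmt(radius_of_gyration(ref_geo), 3),
                    "mobile": _fmt(radius_of_gyration(mob_geo), 3),
                },
            }
    finally:
        flush()
        pkg_logger.removeHandler(log_handler)
        log_handler.close()
    return report


def main_report(config_path: str, log_stream=sys.stderr) -> dict:
    logging.basicConfig(stream=log_stream, level=logging.INFO)
    cfg = AnalysisConfig.from_yaml(config_path)
    return run_report(cfg)
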