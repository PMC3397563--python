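# lobedyn

Comparative structural-dynamics analysis of bi-lobed proteins from
atomic-resolution crystal structures. The package reads PDB coordinate
files (including `ANISOU` anisotropic displacement records and alternate
conformers) and provides:

- **structure_io** — fixed-column PDB reading/writing, residue/atom
  selections with altloc policies, and geometry-ready stripping
  (hydrogens, waters, non-polymer hetero groups, secondary conformers).
- **geometry** — Kabsch least-squares superposition with displacement
  fields over a separate reporting subset, mass-weighted radius of
  gyration, interatomic and atom-to-group distances, and ω peptide
  dihedrals reported on a 0–360° scale.
- **ddm** — difference distance matrices over paired Cα atoms
  (superposition-free detection of concerted inter-lobe movement), with
  block summaries and TSV export.
- **adp** — ADP tensor eigen-analysis: equivalent isotropic B
  ((8π²/3)·tr U), anisotropy A = λ_min/λ_max, and selection of strongly
  anisotropic atoms below a mean − k·SD threshold with their principal
  axes.
- **anm** — anisotropic-network-model normal modes of a Cα network
  (uniform spring constant, 15 Å cutoff by default): Hessian assembly,
  spectra with trivial-mode counting, mode/displacement overlap, and
  compaction-phase orientation; NMD-style export for viewers.
- **synthetic_data** — deterministic generators: a two-lobe Cα toy with a
  tunable hinge, hinge-closed variants, conformer pairs displaced along a
  chosen mode, and planted ANISOU tensors with exact anisotropy.
- **pipeline** — an end-to-end comparative report (superpositions, DDM,
  ADP statistics, modes, overlaps, cleft width, Rg) driven by a YAML
  config, written as `report.json` plus TSV tables.

## Command line

```sh
lobedyn synth two-lobe --seed 1 -o toy.pdb        # bi-lobed Cα toy
lobedyn synth adps --ratio 0.25 toy.pdb -o t.pdb  # plant ANISOU tensors
lobedyn align --fit-sel A:55-58,86-91,96-101:CA ref.pdb mob.pdb
lobedyn measure --distance A:35:N A:98:N file.pdb
lobedyn measure --omega file.pdb
lobedyn measure --rgyr file.pdb
lobedyn ddm a.pdb b.pdb > ddm.tsv
lobedyn adp file.pdb --atoms CA --select-k 0.5
lobedyn anm file.pdb --cutoff 15 --gamma 1 --modes 6 --nmd modes.nmd
lobedyn report --config analysis.yaml
lobedyn fetch 3SNF -o data/3SNF.pdb               # needs network
```

A report config lists the two input files and optional overrides
(selection ranges, ANM cutoff/γ/mode count, ADP k, output directory):

```yaml
reference: 3SNF.pdb
mobile: 1ONC.pdb
outdir: out
anm_cutoff: 15.0
adp_k: 0.5
```

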