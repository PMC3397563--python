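# Fixture data

The fixture-based tests and the full acceptance report expect the
following PDB entries here, in plain PDB format:

- `3SNF.pdb` — onconase·sulfate, 1.1 Å, 100 K (with ANISOU records)
- `1ONC.pdb` — onconase·sulfate, 1.7 Å, room temperature
- `2I5S.pdb` — onconase·d(AUGA) complex, 1.9 Å
- `1YV4.pdb` — M23L onconase·sulfate, 1.51 Å

They are not bundled (no redistribution, and this build environment has no
network access). On a networked machine:

```sh
lobedyn fetch 3SNF -o data/3SNF.pdb
lobedyn fetch 1ONC -o data/1ONC.pdb
lobedyn fetch 2I5S -o data/2I5S.pdb
lobedyn fetch 1YV4 -o data/1YV4.pdb
```
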