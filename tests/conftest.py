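"""Shared fixtures: synthetic toys and a hand-assembled PDB text fixture."""

from pathlib import Path

import numpy as np
import pytest

from lobedyn.structure_io import read_pdb
from lobedyn.synthetic_data import (
    ToyStructureSpec,
    make_hinge_closed,
    make_two_lobe,
    soft_hinge_spec,
)

DATA_DIR = Path(__file__).resolve().parent.parent / "data"

# Mixed-content PDB: protein residues (one with A/B altlocs, one with a
# hydrogen), an N-terminal pyroglutamate-like hetero residue with CA, a
# sulfate and a water.  Column layout follows PDB v3.3.
SAMPLE_PDB = """\
CRYST1   32.230   38.160   68.920  90.00  90.00  90.00 P 21 21 21
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       2.000   2.500   3.000  1.00 11.00           C
ANISOU    2  CA  ALA A   1    10000  10000  10000      0      0      0       C
ATOM      3  C   ALA A   1       3.200   1.800   3.400  1.00 10.50           C
ATOM      4  O   ALA A   1       3.300   0.600   3.300  1.00 12.00           O
ATOM      5  HA  ALA A   1       2.100   3.500   3.100  1.00 10.00           H
ATOM      6  N   SER A   2       4.100   2.500   4.000  1.00 10.00           N
ATOM      7  CA  SER A   2       5.400   2.000   4.400  1.00 10.00           C
ATOM      8  C   SER A   2       6.500   2.900   3.900  1.00 10.00           C
ATOM      9  OG ASER A   2       5.600   0.700   3.900  0.60 10.00           O
ATOM     10  OG BSER A   2       5.500   0.600   4.200  0.40 10.00           O
HETATM   11  CA  PCA A   3       7.700   2.500   4.600  1.00 12.00           C
HETATM   12  N   PCA A   3       7.000   3.500   5.300  1.00 12.00           N
HETATM   13  S   SO4 A 101      10.000  10.000  10.000  0.80 17.00           S
HETATM   14  O1  SO4 A 101      11.200  10.400  10.500  0.80 17.50           O
HETATM   15  O   HOH A 201      15.000  15.000  15.000  1.00 20.00           O
END
"""


@pytest.fixture
def sample_pdb_path(tmp_path):
    p = tmp_path / "sample.pdb"
    p.write_text(SAMPLE_PDB)
    return p


@pytest.fixture
def sample_structure(sample_pdb_path):
    return read_pdb(sample_pdb_path)


@pytest.fixture(scope="session")
def toy_spec():
    return ToyStructureSpec(seed=1)


@pytest.fixture(scope="session")
def toy(toy_spec):
    return make_two_lobe(toy_spec)


@pytest.fixture(scope="session")
def soft_spec():
    return soft_hinge_spec(seed=1)


@pytest.fixture(scope="session")
def soft_toy(soft_spec):
    return make_two_lobe(soft_spec)


@pytest.fixture(scope="session")
def soft_closed(soft_toy, soft_spec):
    return make_hinge_closed(soft_toy, soft_spec, 5.0)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
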