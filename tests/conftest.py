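"""Shared fixtures: tiny on-disk structure/trajectory files, written at test time."""

import numpy as np
import pytest

PDB_3ATOMS = """\
ATOM      1  CA  ALA A   1      10.000  20.000  30.000  1.00  0.00           C
ATOM      2  CA  ALA A   2      11.000  21.000  31.000  1.00  0.00           C
HETATM    3 CL   CLA A   3      12.500  22.500  32.500  1.00  0.00          Cl
END
"""

GRO_2ATOMS = """\
tiny system
    2
    1ALA     CA    1   1.000   2.000   3.000
    2CLA     CL    2   1.500   2.500   3.500
   4.00000   5.00000   6.00000
"""


@pytest.fixture
def pdb_file(tmp_path):
    p = tmp_path / "ref.pdb"
    p.write_text(PDB_3ATOMS)
    return p


@pytest.fixture
def gro_file(tmp_path):
    p = tmp_path / "ref.gro"
    p.write_text(GRO_2ATOMS)
    return p


@pytest.fixture
def xyz_two_frames(tmp_path):
    """Two-frame XYZ (Å) matching the 3-atom PDB topology."""
    p = tmp_path / "run.xyz"
    p.write_text(
        "3\nframe 0\nC 10.0 20.0 30.0\nC 11.0 21.0 31.0\nCl 12.5 22.5 32.5\n"
        "3\nframe 1\nC 10.5 20.5 30.5\nC 11.5 21.5 31.5\nCl 13.0 23.0 33.0\n"
    )
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_structure(n_waters=0, box=None):
    """In-memory structure: one 6-Cα 'hexamer' ring plus optional waters."""
    from porewatch.trajectory_core import Structure

    angles = np.arange(6) * np.pi / 3
    ca = np.column_stack(
        [1.2 * np.cos(angles), 1.2 * np.sin(angles), np.zeros(6)]
    )
    names = ["CA"] * 6
    resnames = ["SER"] * 6
    resids = list(range(1, 7))
    chains = list("ABCDEF")
    coords = [ca]
    for w in range(n_waters):
        names.append("OW")
        resnames.append("SOL")
        resids.append(100 + w)
        chains.append("W")
        coords.append(np.array([[0.1 * w, 0.2 * w, 0.3 * w]]))
    return Structure(
        atom_names=np.array(names, dtype=object),
        res_names=np.array(resnames, dtype=object),
        res_ids=np.array(resids),
        chain_ids=np.array(chains, dtype=object),
        coords=np.vstack(coords),
        box=np.array(box) if box is not None else None,
    )
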