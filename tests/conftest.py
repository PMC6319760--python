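"""Shared fixtures: tiny handwritten PDB files and random toy structures."""

import numpy as np
import pytest

from qstab.structures import Atom, Residue, StructureModel

# A 3-residue mini-peptide with explicit element columns, one hydrogen,
# and a water that loaders must drop.  Coordinates are arbitrary but finite.
THREE_RESIDUE_PDB = """\
HEADER    TOY PEPTIDE
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
ATOM      6  HA  ALA A   1       1.800  -0.500   0.900  1.00  0.00           H
ATOM      7  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      8  CA  GLY A   2       3.980   2.840   0.000  1.00  0.00           C
ATOM      9  C   GLY A   2       5.500   2.700   0.000  1.00  0.00           C
ATOM     10  O   GLY A   2       6.030   1.590   0.000  1.00  0.00           O
ATOM     11  N   TRP A   3       6.200   3.830   0.000  1.00  0.00           N
ATOM     12  CA  TRP A   3       7.660   3.830   0.000  1.00  0.00           C
ATOM     13  C   TRP A   3       8.210   5.250   0.000  1.00  0.00           C
ATOM     14  O   TRP A   3       7.450   6.220   0.000  1.00  0.00           O
ATOM     15  CB  TRP A   3       8.190   3.060  -1.210  1.00  0.00           C
HETATM   16  O   HOH A 101      12.000  12.000  12.000  1.00  0.00           O
END
"""

# Two MODELs of a 1-residue fragment: the second model is shifted +1 A in x.
TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  N   GLY A   1       1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       2.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       3.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       2.251   2.390   0.000  1.00  0.00           O
ENDMDL
END
"""

# Altloc fixture: CA has two altlocs, B with higher occupancy.
ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.458   0.000   0.000  0.40  0.00           C
ATOM      3  CA BSER A   1       1.500   0.100   0.000  0.60  0.00           C
ATOM      4  C   SER A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      5  O   SER A   1       1.251   2.390   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    p = tmp_path / "toy3.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return p


@pytest.fixture
def two_model_pdb(tmp_path):
    p = tmp_path / "two_model.pdb"
    p.write_text(TWO_MODEL_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


def random_structure(n_atoms: int, seed: int, box: float = 12.0,
                     n_residues: int = None) -> StructureModel:
    """Random toy structure: atoms scattered in a box, assigned round-robin
    to residues; used for brute-force oracle comparisons."""
    rng = np.random.default_rng(seed)
    if n_residues is None:
        n_residues = max(2, n_atoms // 3)
    names = ["ALA", "ASP", "PHE", "GLY", "LYS", "LEU", "SER", "TRP"]
    residues = [
        Residue(i, names[i % len(names)], i + 1, " ", "A")
        for i in range(n_residues)
    ]
    atoms = []
    for k in range(n_atoms):
        res = k % n_residues
        atoms.append(
            Atom(
                serial=k + 1,
                name="C" + str(k % 9),
                element="C",
                residue_index=res,
                residue_name=residues[res].name,
                chain_id="A",
                xyz=rng.uniform(0, box, size=3),
            )
        )
    atoms.sort(key=lambda a: (a.residue_index, a.serial))
    # re-serialize in sorted order so serial order matches atom order
    atoms = [
        Atom(i + 1, a.name, a.element, a.residue_index, a.residue_name,
             a.chain_id, a.xyz)
        for i, a in enumerate(atoms)
    ]
    return StructureModel(atoms, residues, source_id=f"random{seed}")


@pytest.fixture
def small_synthetic():
    """A small stable synthetic system (structure + ensemble), fast to build."""
    from qstab.synthetic import SyntheticSystemSpec, build_system

    spec = SyntheticSystemSpec(
        system_id="small", n_replicas=3, n_frames=40, seed=11
    )
    structure, ensemble = build_system(spec)
    return spec, structure, ensemble
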