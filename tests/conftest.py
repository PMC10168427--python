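"""Shared fixtures: hand-written coordinate files and tiny builders."""
import numpy as np
import pytest

from rna_assess.structure_io import Atom, Residue, Structure


def structure_from_points(points, atom_name="C4'", chain="A", start=1,
                          res_name="A", extra_atoms=()):
    """One RNA residue per point, carrying ``atom_name`` (plus optional extra
    atom offsets) — a minimal scaffold for coordinate-level metrics."""
    residues = []
    for i, p in enumerate(np.asarray(points, dtype=float)):
        atoms = [Atom(atom_name, atom_name[0], p)]
        for name, off in extra_atoms:
            atoms.append(Atom(name, name[0], p + np.asarray(off)))
        residues.append(Residue(chain, start + i, res_name, atoms,
                                kind="rna", parent=res_name))
    return Structure("points", residues)


def random_rotation(rng):
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def transform(structure, R=None, t=(0, 0, 0)):
    """Rigidly transformed deep copy of a structure."""
    R = np.eye(3) if R is None else R
    t = np.asarray(t, dtype=float)
    residues = []
    for r in structure.residues:
        atoms = [Atom(a.name, a.element, R @ a.position + t) for a in r.atoms]
        residues.append(Residue(r.chain_id, r.seq_id, r.res_name, atoms,
                                r.insertion_code, r.kind, r.parent))
    return Structure(structure.id + "-moved", residues)


SINGLE_RESIDUE_PDB = """\
ATOM      1  P     G A   1       1.000   2.000   3.000  1.00  0.00           P
ATOM      2  C4'   G A   1       2.500   3.100   3.900  1.00  0.00           C
ATOM      3  N9    G A   1       4.200   2.800   5.100  1.00  0.00           N
ATOM      4  C1'   G A   1       3.300   3.600   4.800  1.00  0.00           C
ATOM      5  H5'   G A   1       0.000   0.000   0.000  1.00  0.00           H
END
"""


@pytest.fixture
def single_residue_pdb(tmp_path):
    path = tmp_path / "single.pdb"
    path.write_text(SINGLE_RESIDUE_PDB)
    return path


@pytest.fixture
def three_model_pdb(tmp_path):
    blocks = []
    for m in range(1, 4):
        blocks.append(f"MODEL     {m:4d}")
        blocks.append(
            f"ATOM      1  C4'   A A   1       {m:.3f}   0.000   0.000"
            "  1.00  0.00           C")
        blocks.append(
            f"ATOM      2  C1'   A A   1       {m + 1:.3f}   1.000   0.000"
            "  1.00  0.00           C")
        blocks.append("ENDMDL")
    blocks.append("END")
    path = tmp_path / "models.pdb"
    path.write_text("\n".join(blocks) + "\n")
    return path
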