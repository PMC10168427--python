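"""Macromolecular structure reading/writing and residue correspondence.

Structures are held as a flat, ordered list of residues grouped by chain,
each residue carrying its heavy atoms with coordinates in Å.  Hydrogens and
waters are discarded on read; modified nucleotides are mapped to their parent
base (the original residue name is retained in ``res_name``).  PDB files with
multiple MODEL blocks and multi-model mmCIF files become :class:`Ensemble`
objects with one :class:`Structure` per model.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Ensemble",
    "ResidueCorrespondence",
    "PairedCoordinates",
    "StructureError",
    "StructureParseError",
    "EmptyStructureError",
    "NoOverlapError",
    "read_structure",
    "write_pdb",
    "build_correspondence",
    "coordinates_for",
]


class StructureError(Exception):
    """Base class for structure-handling failures."""


class StructureParseError(StructureError):
    """The file could not be parsed under the requested dialect."""


class EmptyStructureError(StructureError):
    """No residues survived filtering (hydrogens/waters removed)."""


class NoOverlapError(StructureError):
    """A correspondence or atom pairing produced zero pairs."""


# Parent-base mapping for common modified nucleotides.  Unmapped polymer
# HETATM residues become kind="other" and are excluded from RNA metrics.
MODIFIED_PARENT = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "PSU": "U", "H2U": "U", "4SU": "U", "5MU": "U", "OMU": "U", "UR3": "U",
    "DHU": "U", "3MU": "U",
    "1MA": "A", "2MA": "A", "6MA": "A", "OMA": "A", "A2M": "A", "MA6": "A",
    "5MC": "C", "OMC": "C", "4OC": "C", "M4C": "C",
    "2MG": "G", "M2G": "G", "7MG": "G", "OMG": "G", "1MG": "G", "G7M": "G",
    "I": "G", "IG": "G",
}

AMINO3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}

_WATER = {"HOH", "WAT", "DOD", "H2O"}


@dataclasses.dataclass
class Atom:
    """A heavy atom: label, element symbol and position in Å."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")


@dataclasses.dataclass
class Residue:
    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[Atom]
    insertion_code: str = ""
    kind: str = "other"  # rna | protein | other
    parent: str = ""     # one-letter parent code for rna/protein

    @property
    def key(self) -> str:
        """Stable residue key ``chain:seqid[:icode]``."""
        base = f"{self.chain_id}:{self.seq_id}"
        return f"{base}:{self.insertion_code}" if self.insertion_code else base

    @property
    def id_tuple(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}


@dataclasses.dataclass
class Structure:
    id: str
    residues: list[Residue]

    def __post_init__(self):
        if not self.residues:
            raise EmptyStructureError(f"structure {self.id!r} has no residues")

    def rna_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "rna"]

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "protein"]

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def heavy_atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclasses.dataclass
class Ensemble:
    """One or more conformations read from a single coordinate file."""

    label: str
    members: list[Structure]

    def __post_init__(self):
        if not self.members:
            raise EmptyStructureError(f"ensemble {self.label!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i) -> Structure:
        return self.members[i]


@dataclasses.dataclass
class ResidueCorrespondence:
    """Index pairs (model residue index, reference residue index)."""

    pairs: list[tuple[int, int]]
    mode: str

    def __post_init__(self):
        mi = [p[0] for p in self.pairs]
        ri = [p[1] for p in self.pairs]
        if sorted(set(mi)) != mi or sorted(set(ri)) != ri:
            raise ValueError("correspondence pairs must be strictly increasing "
                             "and unique on both sides")

    def __len__(self) -> int:
        return len(self.pairs)

    def transposed(self) -> "ResidueCorrespondence":
        return ResidueCorrespondence([(j, i) for i, j in self.pairs], self.mode)


@dataclasses.dataclass
class PairedCoordinates:
    """Equal-length coordinate arrays for corresponded atoms."""

    model_xyz: np.ndarray      # (n, 3)
    reference_xyz: np.ndarray  # (n, 3)
    residue_pairs: list[tuple[int, int]]  # per-row correspondence entry

    def __len__(self) -> int:
        return len(self.model_xyz)


def _classify(res_name: str) -> tuple[str, str]:
    if res_name in MODIFIED_PARENT:
        return "rna", MODIFIED_PARENT[res_name]
    if res_name in AMINO3:
        return "protein", AMINO3[res_name]
    return "other", ""


def _from_gemmi_model(model, label: str, index: int) -> Structure | None:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            name = res.name.strip()
            if name in _WATER:
                continue
            # altloc: keep highest occupancy, ties broken by altloc label order
            best: dict[str, object] = {}
            for at in res:
                if at.element.is_hydrogen:
                    continue
                prev = best.get(at.name)
                if prev is None or (at.occ, -ord(at.altloc or "~")) > (
                        prev.occ, -ord(prev.altloc or "~")):
                    best[at.name] = at
            atoms = [
                Atom(a.name, a.element.name,
                     np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in best.values()
            ]
            if not atoms:
                continue
            kind, parent = _classify(name)
            residues.append(Residue(
                chain_id=chain.name, seq_id=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                res_name=name, atoms=atoms, kind=kind, parent=parent))
    if not residues:
        return None
    return Structure(id=f"{label}#{index}" if index else label, residues=residues)


def read_structure(path: str | Path,
                   format: Literal["pdb", "mmcif", "auto"] = "auto") -> Ensemble:
    """Read a PDB or mmCIF file into an :class:`Ensemble`.

    Every MODEL record (PDB) or model block (mmCIF) becomes one ensemble
    member.  Hydrogens and waters are dropped; modified nucleotides are mapped
    to their parent base with the original residue name retained.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"file not found: {path}")
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except Exception as exc:  # gemmi raises RuntimeError with line info
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    label = path.stem
    members = []
    for i, model in enumerate(st):
        s = _from_gemmi_model(model, label, i)
        if s is not None:
            members.append(s)
    if not members:
        raise EmptyStructureError(
            f"{path}: no residues left after removing hydrogens and waters")
    return Ensemble(label=label, members=members)


def write_pdb(path: str | Path, structure: Structure | Ensemble) -> None:
    """Write a minimal PDB file (ATOM records, MODEL/ENDMDL for ensembles)."""
    members = structure.members if isinstance(structure, Ensemble) else [structure]
    lines: list[str] = []
    multi = len(members) > 1
    for m_i, st in enumerate(members, start=1):
        if multi:
            lines.append(f"MODEL     {m_i:4d}")
        serial = 1
        for res in st.residues:
            for at in res.atoms:
                name = at.name
                # standard alignment: 1-3 char names start in column 14
                field = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = at.position
                lines.append(
                    f"ATOM  {serial:5d} {field:<4s}{'':1s}{res.res_name:>3s} "
                    f"{res.chain_id[:1]:1s}{res.seq_id:4d}{res.insertion_code[:1] or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {at.element:>2s}")
                serial += 1
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# residue correspondence
# ---------------------------------------------------------------------------

def build_correspondence(model: Structure, reference: Structure,
                         mode: Literal["by_numbering", "by_sequence"] = "by_numbering",
                         ) -> ResidueCorrespondence:
    """Establish a fixed residue-residue correspondence.

    ``by_numbering`` pairs residues sharing (chain, author seq id, insertion
    code); ``by_sequence`` pairs chains via global alignment of one-letter
    sequences (match +1, mismatch -1, gap -2).  Unpaired residues are
    excluded.
    """
    if mode == "by_numbering":
        ref_index = {}
        for j, r in enumerate(reference.residues):
            ref_index.setdefault(r.id_tuple, j)
        pairs = []
        last_j = -1
        for i, r in enumerate(model.residues):
            j = ref_index.get(r.id_tuple)
            if j is None or r.kind != reference.residues[j].kind:
                continue
            if j > last_j:
                pairs.append((i, j))
                last_j = j
    elif mode == "by_sequence":
        pairs = _align_by_sequence(model, reference)
    else:
        raise ValueError(f"unknown correspondence mode {mode!r}")
    if not pairs:
        raise NoOverlapError(
            f"no residue overlap between {model.id!r} and {reference.id!r}")
    return ResidueCorrespondence(pairs, mode)


def _chain_blocks(st: Structure) -> list[tuple[str, list[int]]]:
    blocks: list[tuple[str, list[int]]] = []
    for i, r in enumerate(st.residues):
        if blocks and blocks[-1][0] == r.chain_id:
            blocks[-1][1].append(i)
        else:
            blocks.append((r.chain_id, [i]))
    return blocks


def _align_by_sequence(model: Structure, reference: Structure) -> list[tuple[int, int]]:
    from Bio import Align

    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=-1, open_gap_score=-2,
                                    extend_gap_score=-2)
    mblocks = _chain_blocks(model)
    rblocks = _chain_blocks(reference)
    # pair chains by id when shared, otherwise by order of appearance
    rbyid = {c: idx for c, idx in rblocks}
    if all(c in rbyid for c, _ in mblocks):
        block_pairs = [(idx, rbyid[c]) for c, idx in mblocks]
    else:
        block_pairs = [(mi, ri) for (_, mi), (_, ri) in zip(mblocks, rblocks)]
    pairs: list[tuple[int, int]] = []
    for midx, ridx in block_pairs:
        mseq = "".join(model.residues[i].parent or "X" for i in midx)
        rseq = "".join(reference.residues[j].parent or "X" for j in ridx)
        if not mseq or not rseq:
            continue
        aln = aligner.align(mseq, rseq)[0]
        for (ms, me), (rs, re) in zip(*aln.aligned):
            for k in range(me - ms):
                i, j = midx[ms + k], ridx[rs + k]
                if model.residues[i].kind == reference.residues[j].kind:
                    pairs.append((i, j))
    pairs.sort()
    return pairs


_NAMED_SELECTIONS = {"C4'", "C3'", "P", "CA"}


def coordinates_for(model: Structure, reference: Structure,
                    correspondence: ResidueCorrespondence,
                    atom_selection: str = "all_heavy") -> PairedCoordinates:
    """Extract paired coordinate arrays over a correspondence.

    For a named-atom selection (``C4'``, ``C3'``, ``P``) a row is emitted only
    when the atom exists in both residues of a pair; for ``all_heavy`` atoms
    are matched by name within each residue pair.
    """
    P: list[np.ndarray] = []
    Q: list[np.ndarray] = []
    rows: list[tuple[int, int]] = []
    for i, j in correspondence.pairs:
        rm, rr = model.residues[i], reference.residues[j]
        if atom_selection == "all_heavy":
            common = sorted(rm.atom_names() & rr.atom_names())
            for name in common:
                P.append(rm.atom(name).position)
                Q.append(rr.atom(name).position)
                rows.append((i, j))
        else:
            am, ar = rm.atom(atom_selection), rr.atom(atom_selection)
            if am is not None and ar is not None:
                P.append(am.position)
                Q.append(ar.position)
                rows.append((i, j))
    if not P:
        raise NoOverlapError(
            f"no common atoms for selection {atom_selection!r}")
    return PairedCoordinates(np.array(P), np.array(Q), rows)
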