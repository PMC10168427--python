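"""RNA-protein complex assessment: contact maps, contact MCC and
folding-pattern strings.

A contact is any nucleotide / amino-acid pair with heavy atoms within a
cutoff (5 Å by default).  Predicted contact maps are scored against the
reference map with the Matthews correlation coefficient.  The RNA-protein
binding arrangement is summarized superposition-free as a folding pattern:
contacted RNA regions in 5'->3' order, each labelled by the protein entity
(e.g. a homodimer) it contacts, with '-' marking expected-but-unbound
regions.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np

from .structure_io import Residue, Structure

__all__ = [
    "ContactMap",
    "FoldingPattern",
    "contact_map",
    "contact_mcc",
    "folding_pattern",
    "pattern_match",
    "ENTITY_LETTERS",
]

ENTITY_LETTERS = "BRGYOPMC"  # blue, red, green, yellow, ... in assignment order


@dataclasses.dataclass
class ContactMap:
    """Binary RNA-residue x protein-residue contact matrix."""

    matrix: np.ndarray          # bool (n_rna, n_protein)
    rna_keys: list[str]
    protein_keys: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (len(self.rna_keys), len(self.protein_keys)):
            raise ValueError("contact matrix shape does not match axis keys")


def contact_map(complex_structure: Structure, cutoff: float = 5.0
                ) -> ContactMap:
    """All-against-all nucleotide/amino-acid contact map at ``cutoff`` Å.

    Computed with a KD-tree over heavy atoms; equal to the brute-force
    minimum-interatomic-distance definition.
    """
    rna = complex_structure.rna_residues()
    protein = complex_structure.protein_residues()
    if not rna or not protein:
        raise ValueError("complex must contain both RNA and protein residues")
    from scipy.spatial import cKDTree

    r_xyz, r_idx = [], []
    for i, res in enumerate(rna):
        for a in res.atoms:
            r_xyz.append(a.position)
            r_idx.append(i)
    p_xyz, p_idx = [], []
    for j, res in enumerate(protein):
        for a in res.atoms:
            p_xyz.append(a.position)
            p_idx.append(j)
    mat = np.zeros((len(rna), len(protein)), dtype=bool)
    tree = cKDTree(np.asarray(p_xyz))
    for xyz, i in zip(r_xyz, r_idx):
        for k in tree.query_ball_point(xyz, cutoff):
            mat[i, p_idx[k]] = True
    return ContactMap(mat, [r.key for r in rna], [r.key for r in protein])


def contact_mcc(predicted: ContactMap, reference: ContactMap) -> float:
    """Matthews correlation coefficient between two contact maps.

    Maps are compared over the union of their residue keys; residues absent
    from one structure contribute all-zero rows/columns there, so hallucinated
    and missing chains are punished symmetrically.  Returns 0 when either
    flattened map is constant.
    """
    if not (set(predicted.rna_keys) & set(reference.rna_keys)) or \
            not (set(predicted.protein_keys) & set(reference.protein_keys)):
        raise ValueError("contact maps share no residue keys")

    def union(a: list[str], b: list[str]) -> list[str]:
        return list(dict.fromkeys(a + b))

    rna = union(reference.rna_keys, predicted.rna_keys)
    prot = union(reference.protein_keys, predicted.protein_keys)

    def expand(m: ContactMap) -> np.ndarray:
        out = np.zeros((len(rna), len(prot)), dtype=bool)
        ri = {k: i for i, k in enumerate(rna)}
        pi = {k: i for i, k in enumerate(prot)}
        for i, rk in enumerate(m.rna_keys):
            for j, pk in enumerate(m.protein_keys):
                if m.matrix[i, j]:
                    out[ri[rk], pi[pk]] = True
        return out

    p = expand(predicted).ravel()
    r = expand(reference).ravel()
    tp = int(np.sum(p & r))
    tn = int(np.sum(~p & ~r))
    fp = int(np.sum(p & ~r))
    fn = int(np.sum(~p & r))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


# ---------------------------------------------------------------------------
# folding patterns
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FoldingPattern:
    """String over {B, R, G, ..., -} describing the 5'->3' order in which RNA
    regions contact distinct protein entities."""

    pattern: str
    regions: list[tuple[int, int]]  # (start, end) RNA positions, bound regions

    def letters(self) -> str:
        return self.pattern.replace("-", "")


def _segment(positions: Sequence[int], gap_threshold: int
             ) -> list[tuple[int, int]]:
    """Contiguous regions of contacted positions; a gap larger than the
    threshold starts a new region."""
    regions = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p - prev > gap_threshold:
            regions.append((start, prev))
            start = p
        prev = p
    regions.append((start, prev))
    return regions


def folding_pattern(complex_structure: Structure,
                    protein_entities: Sequence[Sequence[str]],
                    expected_regions: int | None = None,
                    gap_threshold: int = 10,
                    cutoff: float = 5.0) -> FoldingPattern:
    """Classify the RNA-protein binding arrangement as a pattern string.

    ``protein_entities`` partitions protein chain ids into entities (for
    example homodimers).  RNA contact positions are segmented into regions
    (a gap of more than ``gap_threshold`` nucleotides starts a new region),
    regions are ordered 5'->3', entities are lettered B, R, G, ... by the
    order of their most-5' contacted region, and the pattern lists the letter
    of the entity each region contacts.  When ``expected_regions`` exceeds the
    number of bound regions, '-' placeholders are inserted at the largest
    uncontacted gaps.
    """
    cm = contact_map(complex_structure, cutoff)
    rna = complex_structure.rna_residues()
    protein = complex_structure.protein_residues()
    chain_of = {r.key: r.chain_id for r in protein}
    entity_of_chain: dict[str, int] = {}
    for e, chains in enumerate(protein_entities):
        for c in chains:
            entity_of_chain[c] = e

    # sequence position (5'->3') per RNA residue: author numbering within a
    # chain, with chain changes offset far enough to always start a region
    position_of: dict[int, int] = {}
    offset = 0
    prev_chain = None
    prev_seq = 0
    for i, res in enumerate(rna):
        if prev_chain is not None and res.chain_id != prev_chain:
            offset += prev_seq + 10 * (gap_threshold + 1)
        position_of[i] = offset + res.seq_id
        prev_chain, prev_seq = res.chain_id, offset + res.seq_id

    # per RNA sequence position, the set of entities it contacts
    contacts_at: dict[int, set[int]] = {}
    for i, rk in enumerate(cm.rna_keys):
        for j, pk in enumerate(cm.protein_keys):
            if cm.matrix[i, j]:
                ent = entity_of_chain.get(chain_of[pk])
                if ent is not None:
                    contacts_at.setdefault(position_of[i], set()).add(ent)
    if not contacts_at:
        warnings.warn("no RNA-protein contacts; pattern is all unbound")
        n = expected_regions or 0
        return FoldingPattern("-" * n, [])

    positions = sorted(contacts_at)
    regions = _segment(positions, gap_threshold)
    # majority entity per region
    region_entity = []
    for start, end in regions:
        votes: dict[int, int] = {}
        for p in range(start, end + 1):
            for e in contacts_at.get(p, ()):
                votes[e] = votes.get(e, 0) + 1
        region_entity.append(max(votes, key=lambda e: (votes[e], -e)))
    # letters by order of each entity's most-5' region
    letter_of: dict[int, str] = {}
    for e in region_entity:
        if e not in letter_of:
            letter_of[e] = ENTITY_LETTERS[len(letter_of)]
    letters = [letter_of[e] for e in region_entity]

    if expected_regions is not None and expected_regions > len(regions):
        n_unbound = expected_regions - len(regions)
        # candidate slots: between consecutive bound regions, sized by gap
        gaps = []
        for s in range(1, len(regions)):
            gap = regions[s][0] - regions[s - 1][1]
            gaps.append((gap, s))
        gaps.sort(reverse=True)
        slots = sorted(s for _, s in gaps[:n_unbound])
        out = []
        for idx, ch in enumerate(letters):
            while slots and slots[0] == idx:
                out.append("-")
                slots.pop(0)
            out.append(ch)
        out.extend("-" * len(slots))
        pattern = "".join(out)
    else:
        pattern = "".join(letters)
    return FoldingPattern(pattern, regions)


def pattern_match(predicted: FoldingPattern | str,
                  reference: FoldingPattern | str) -> str:
    """Compare folding patterns.

    ``exact`` when the strings are equal; ``order_correct_unbound_wrong``
    when the entity letters agree in order but the '-' placement differs;
    ``mismatch`` otherwise.
    """
    p = predicted.pattern if isinstance(predicted, FoldingPattern) else predicted
    r = reference.pattern if isinstance(reference, FoldingPattern) else reference
    if not p or not r:
        raise ValueError("patterns must be non-empty")
    if p == r:
        return "exact"
    if p.replace("-", "") == r.replace("-", ""):
        return "order_correct_unbound_wrong"
    return "mismatch"
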