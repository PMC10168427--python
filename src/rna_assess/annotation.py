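"""Geometric annotation of base pairs and stacking, and torsion computation.

Base pairs are classified at the granularity the interaction-fidelity metrics
need: Watson-Crick-type (WC — AU, GC or GU in near-coplanar geometry hydrogen
bonded through the canonical WC edges) versus everything else (NWC).
Stacking contacts are detected from base-plane geometry.  The thresholds are
this module's own calibrated definition and live in one config object so they
can be tuned; they are validated against the in-package duplex generator,
which knows its designed pairing exactly.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable

import numpy as np

from .structure_io import Residue, Structure

__all__ = [
    "AnnotationThresholds",
    "BasePair",
    "StackingContact",
    "InteractionNetwork",
    "TorsionSet",
    "annotate",
    "compute_torsions",
    "dihedral",
    "RING_ATOMS",
    "DONORS",
    "ACCEPTORS",
    "WC_EDGE",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}

RING_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

# polar base atoms able to donate / accept hydrogen bonds (parent bases)
DONORS = {"A": {"N6"}, "G": {"N1", "N2"}, "C": {"N4"}, "U": {"N3"}}
ACCEPTORS = {
    "A": {"N1", "N3", "N7"},
    "G": {"O6", "N3", "N7"},
    "C": {"N3", "O2"},
    "U": {"O2", "O4"},
}

# atoms of the canonical Watson-Crick edge (N1/N3-centred)
WC_EDGE = {
    "A": {"N1", "N6"},
    "G": {"N1", "N2", "O6"},
    "C": {"N3", "N4", "O2"},
    "U": {"N3", "O2", "O4"},
}

_WC_COMBOS = {frozenset(("A", "U")), frozenset(("G", "C")), frozenset(("G", "U"))}


@dataclasses.dataclass
class AnnotationThresholds:
    """Geometric windows used for pair and stack detection (Å / degrees)."""

    c1c1_wc: tuple[float, float] = (8.0, 12.0)
    c1c1_general: tuple[float, float] = (5.0, 14.0)
    hbond_max: float = 3.4
    min_hbonds: int = 2
    pair_plane_angle_max: float = 35.0
    pair_plane_sep_max: float = 2.5
    stack_sep: tuple[float, float] = (2.8, 5.5)
    stack_angle_max: float = 30.0
    stack_offset_max: float = 4.0


DEFAULT_THRESHOLDS = AnnotationThresholds()


@dataclasses.dataclass(frozen=True)
class BasePair:
    i: str
    j: str
    category: str  # "WC" | "NWC"

    def edge(self) -> frozenset[str]:
        return frozenset((self.i, self.j))


@dataclasses.dataclass(frozen=True)
class StackingContact:
    i: str
    j: str

    def edge(self) -> frozenset[str]:
        return frozenset((self.i, self.j))


@dataclasses.dataclass
class InteractionNetwork:
    """Annotated WC / NWC / stacking contacts of one structure.

    Residues are identified by their stable keys ``chain:seqid[:icode]``.
    """

    wc: set[frozenset[str]] = dataclasses.field(default_factory=set)
    nwc: set[frozenset[str]] = dataclasses.field(default_factory=set)
    stack: set[frozenset[str]] = dataclasses.field(default_factory=set)

    def category(self, name: str) -> set[frozenset[str]]:
        name = name.upper()
        if name == "WC":
            return set(self.wc)
        if name == "NWC":
            return set(self.nwc)
        if name == "STACK":
            return set(self.stack)
        if name == "BPS":
            return self.wc | self.nwc
        if name == "ALL":
            return self.wc | self.nwc | self.stack
        raise ValueError(f"unknown interaction category {name!r}")

    def to_dict(self) -> dict[str, list[list[str]]]:
        conv = lambda s: sorted(sorted(e) for e in s)
        return {"wc": conv(self.wc), "nwc": conv(self.nwc),
                "stack": conv(self.stack)}


def _base_frame(res: Residue) -> tuple[np.ndarray, np.ndarray] | None:
    """Centroid and unit normal of the base ring (best-fit plane)."""
    names = RING_ATOMS.get(res.parent)
    if names is None:
        return None
    pts = [res.atom(n).position for n in names if res.atom(n) is not None]
    if len(pts) < 3:
        return None
    pts = np.asarray(pts)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    c = abs(float(np.dot(n1, n2)))
    return math.degrees(math.acos(min(1.0, c)))


def _hbond_contacts(ra: Residue, rb: Residue, max_d: float
                    ) -> list[tuple[str, str, float]]:
    """Donor-acceptor base-atom contacts between two residues."""
    out = []
    for d_res, a_res, flip in ((ra, rb, False), (rb, ra, True)):
        for dn in DONORS[d_res.parent]:
            da = d_res.atom(dn)
            if da is None:
                continue
            for an in ACCEPTORS[a_res.parent]:
                aa = a_res.atom(an)
                if aa is None:
                    continue
                d = float(np.linalg.norm(da.position - aa.position))
                if d <= max_d:
                    out.append((an, dn, d) if flip else (dn, an, d))
    return out


def annotate(structure: Structure,
             thresholds: AnnotationThresholds = DEFAULT_THRESHOLDS
             ) -> InteractionNetwork:
    """Detect WC/NWC base pairs and stacking contacts geometrically.

    A pair requires a C1'-C1' distance inside the category window, at least
    two donor-acceptor base-atom contacts, near-coplanar base planes and a
    small vertical plane separation.  WC is assigned only to AU/GC/GU parent
    combinations hydrogen-bonded through the canonical WC-edge atoms.
    Stacking requires parallel planes at van-der-Waals separation with a
    bounded lateral ring offset, and is mutually exclusive with pairing.
    """
    t = thresholds
    rna = [r for r in structure.residues if r.kind == "rna"]
    frames: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    c1: dict[int, np.ndarray] = {}
    usable = []
    for idx, res in enumerate(rna):
        fr = _base_frame(res)
        if fr is None:
            warnings.warn(f"residue {res.key} lacks base ring atoms; skipped")
            continue
        frames[idx] = fr
        a = res.atom("C1'")
        c1[idx] = a.position if a is not None else fr[0]
        usable.append(idx)

    net = InteractionNetwork()
    from scipy.spatial import cKDTree

    if not usable:
        return net
    cents = np.array([frames[i][0] for i in usable])
    tree = cKDTree(cents)
    for ia, ib in sorted(tree.query_pairs(15.0)):
        i, j = usable[ia], usable[ib]
        ra, rb = rna[i], rna[j]
        ca, na = frames[i]
        cb, nb = frames[j]
        d_c1 = float(np.linalg.norm(c1[i] - c1[j]))
        angle = _plane_angle(na, nb)
        # vertical separation measured along the mean plane normal
        mean_n = na + (nb if np.dot(na, nb) > 0 else -nb)
        mean_n /= np.linalg.norm(mean_n)
        dvec = cb - ca
        sep = abs(float(np.dot(dvec, mean_n)))
        lateral = float(np.linalg.norm(dvec - np.dot(dvec, mean_n) * mean_n))

        is_pair = False
        combo = frozenset((ra.parent, rb.parent))
        lo, hi = t.c1c1_general
        if lo <= d_c1 <= hi and angle <= t.pair_plane_angle_max \
                and sep <= t.pair_plane_sep_max:
            contacts = _hbond_contacts(ra, rb, t.hbond_max)
            if len(contacts) >= t.min_hbonds:
                is_pair = True
                wlo, whi = t.c1c1_wc
                wc_contacts = [
                    (dn, an) for dn, an, _ in contacts
                    if {dn, an} <= WC_EDGE[ra.parent] | WC_EDGE[rb.parent]
                    and (dn in WC_EDGE[ra.parent] and an in WC_EDGE[rb.parent]
                         or dn in WC_EDGE[rb.parent] and an in WC_EDGE[ra.parent])
                ]
                if combo in _WC_COMBOS and wlo <= d_c1 <= whi \
                        and len(wc_contacts) >= t.min_hbonds:
                    net.wc.add(frozenset((ra.key, rb.key)))
                else:
                    net.nwc.add(frozenset((ra.key, rb.key)))
        if not is_pair:
            slo, shi = t.stack_sep
            if slo <= sep <= shi and angle <= t.stack_angle_max \
                    and lateral <= t.stack_offset_max:
                net.stack.add(frozenset((ra.key, rb.key)))
    return net


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

TORSION_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
             ) -> float:
    """Signed dihedral angle in degrees in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


@dataclasses.dataclass
class TorsionSet:
    """Backbone/glycosidic torsions per residue, degrees in (-180, 180].

    Undefined angles (missing atoms, chain termini) are ``None``.
    """

    angles: dict[str, dict[str, float | None]]  # residue key -> name -> value

    def get(self, key: str, name: str) -> float | None:
        return self.angles.get(key, {}).get(name)


def _pos(res: Residue | None, name: str) -> np.ndarray | None:
    if res is None:
        return None
    a = res.atom(name)
    return None if a is None else a.position


def compute_torsions(structure: Structure) -> TorsionSet:
    """Standard RNA backbone torsions plus glycosidic chi.

    chi uses O4'-C1'-N9-C4 for purines and O4'-C1'-N1-C2 for pyrimidines.
    Missing atoms or chain termini yield undefined angles, never exceptions.
    """
    rna = [r for r in structure.residues if r.kind == "rna"]
    out: dict[str, dict[str, float | None]] = {}
    for idx, res in enumerate(rna):
        prev = rna[idx - 1] if idx > 0 and rna[idx - 1].chain_id == res.chain_id else None
        nxt = rna[idx + 1] if idx + 1 < len(rna) and rna[idx + 1].chain_id == res.chain_id else None
        if res.parent in PURINES:
            chi_atoms = ((res, "O4'"), (res, "C1'"), (res, "N9"), (res, "C4"))
        else:
            chi_atoms = ((res, "O4'"), (res, "C1'"), (res, "N1"), (res, "C2"))
        defs = {
            "alpha": ((prev, "O3'"), (res, "P"), (res, "O5'"), (res, "C5'")),
            "beta": ((res, "P"), (res, "O5'"), (res, "C5'"), (res, "C4'")),
            "gamma": ((res, "O5'"), (res, "C5'"), (res, "C4'"), (res, "C3'")),
            "delta": ((res, "C5'"), (res, "C4'"), (res, "C3'"), (res, "O3'")),
            "epsilon": ((res, "C4'"), (res, "C3'"), (res, "O3'"), (nxt, "P")),
            "zeta": ((res, "C3'"), (res, "O3'"), (nxt, "P"), (nxt, "O5'")),
            "chi": chi_atoms,
        }
        values: dict[str, float | None] = {}
        for name, spec in defs.items():
            pts = [_pos(r, n) for r, n in spec]
            values[name] = None if any(p is None for p in pts) else dihedral(*pts)
        out[res.key] = values
    return TorsionSet(out)
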