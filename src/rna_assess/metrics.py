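"""Per-model accuracy metrics for RNA structure assessment.

Global-fold metrics (RMSD after optimal superposition, GDT_TS on C4' atoms at
1/2/4/8 Å, TM-score with the length-dependent d0), local metrics (lDDT
without stereochemical penalty, the interaction-network-fidelity INF family,
Deformation Index and Deformation Profile, mean circular torsion deviation
MCQ) and a van-der-Waals clashscore.

All superposition-based metrics operate on a fixed residue-residue
correspondence; lDDT and MCQ are superposition-free by construction.
"""
from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Sequence

import numpy as np

from .annotation import (InteractionNetwork, TorsionSet, annotate,
                         compute_torsions)
from .structure_io import (NoOverlapError, PairedCoordinates,
                           ResidueCorrespondence, Structure, coordinates_for)

__all__ = [
    "SuperpositionResult",
    "MetricReport",
    "DeformationProfile",
    "DegenerateInputError",
    "superpose",
    "rmsd_heavy",
    "gdt_ts",
    "tm_score",
    "tm_d0",
    "lddt_rna",
    "inf",
    "deformation_index",
    "deformation_profile",
    "clashscore",
    "mcq",
    "compute_report",
    "VDW_RADII",
]

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
LDDT_INCLUSION_RADIUS = 15.0
CLASH_OVERLAP = 0.4
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80}

BACKBONE_ATOMS = {"P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'",
                  "C3'", "O3'", "C2'", "O2'", "C1'"}


class DegenerateInputError(ValueError):
    """Too few or collinear points for a well-defined superposition."""


@dataclasses.dataclass
class SuperpositionResult:
    rotation: np.ndarray   # (3, 3), proper
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def superpose(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of P onto Q (Kabsch, proper rotation).

    Returns rotation R and translation t minimizing ``|R P + t - Q|``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    if len(P) < 3:
        raise DegenerateInputError("need at least 3 points to superpose")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    s = np.linalg.svd(Pc, compute_uv=False)
    if s[1] < 1e-8 * max(1.0, s[0]):
        raise DegenerateInputError("points are collinear")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return SuperpositionResult(R, t, rmsd)


def rmsd_heavy(model: Structure, reference: Structure,
               corr: ResidueCorrespondence) -> float:
    """All-heavy-atom RMSD after optimal superposition."""
    pc = coordinates_for(model, reference, corr, "all_heavy")
    return superpose(pc.model_xyz, pc.reference_xyz).rmsd


# ---------------------------------------------------------------------------
# superposition search shared by GDT and TM-score
# ---------------------------------------------------------------------------

def _seed_superpositions(P: np.ndarray, Q: np.ndarray,
                         windows: Sequence[int] = (3, 5, 7)
                         ) -> Iterable[SuperpositionResult]:
    n = len(P)
    try:
        yield superpose(P, Q)
    except DegenerateInputError:
        pass
    for w in windows:
        if w > n:
            continue
        for start in range(0, n - w + 1):
            sl = slice(start, start + w)
            try:
                yield superpose(P[sl], Q[sl])
            except DegenerateInputError:
                continue
    if n <= 10:  # short chains: seed every 3-point frame exhaustively
        for idx in itertools.combinations(range(n), 3):
            try:
                yield superpose(P[list(idx)], Q[list(idx)])
            except DegenerateInputError:
                continue


def _refinement_subsets(d: np.ndarray, n: int) -> Iterable[np.ndarray]:
    """Candidate subsets derived from one distance vector: inliers at each
    GDT cutoff plus the k nearest pairs for a ladder of k values."""
    order = np.argsort(d, kind="stable")
    if n <= 32:
        ks = range(3, n + 1)
    else:  # coarser ladder for long chains
        ks = sorted({3, 4, 5, 7} | {int(round(n * f))
                                    for f in (0.1, 0.2, 0.35, 0.5, 0.7, 0.9, 1.0)})
    for k in ks:
        if 3 <= k <= n:
            yield order[:k]
    for c in GDT_CUTOFFS:
        inl = np.nonzero(d <= c)[0]
        if len(inl) >= 3:
            yield inl


def gdt_ts(model: Structure, reference: Structure, corr: ResidueCorrespondence,
           atom: str = "C4'") -> float:
    """Global distance test (total score), percent.

    For each cutoff (1, 2, 4, 8 Å) the search maximizes the fraction of
    corresponded atoms superposable within the cutoff.  Seeds come from every
    contiguous window of 3, 5 and 7 pairs plus the global superposition; each
    seed is refined by iterating superposition on its inlier sets and on the
    k-nearest-pair prefixes of its distance ordering.
    """
    pc = coordinates_for(model, reference, corr, atom)
    P, Q = pc.model_xyz, pc.reference_xyz
    n = len(P)
    if n < 3:
        raise DegenerateInputError("need >= 3 matched atoms for GDT")
    best = {c: 0 for c in GDT_CUTOFFS}
    for seed in _seed_superpositions(P, Q):
        frontier = [seed]
        seen: set[bytes] = set()
        for _ in range(3):  # refinement rounds per seed
            nxt = []
            for sup in frontier:
                d = np.linalg.norm(sup.apply(P) - Q, axis=1)
                for c in GDT_CUTOFFS:
                    best[c] = max(best[c], int((d <= c).sum()))
                for idx in _refinement_subsets(d, n):
                    key = idx.astype(np.int32).tobytes()
                    if key in seen:
                        continue
                    seen.add(key)
                    try:
                        nxt.append(superpose(P[idx], Q[idx]))
                    except DegenerateInputError:
                        continue
            if not nxt:
                break
            # keep the most promising refinements to bound the work
            scored = []
            for sup in nxt:
                d = np.linalg.norm(sup.apply(P) - Q, axis=1)
                score = sum(int((d <= c).sum()) for c in GDT_CUTOFFS)
                for c in GDT_CUTOFFS:
                    best[c] = max(best[c], int((d <= c).sum()))
                scored.append((score, sup))
            scored.sort(key=lambda t: -t[0])
            frontier = [s for _, s in scored[:5]]
    return 25.0 * sum(best[c] / n for c in GDT_CUTOFFS)


def tm_d0(L: int) -> float:
    """Length-dependent TM-score distance scale for RNA, floored at 0.3 Å."""
    if L < 1:
        raise ValueError("reference length must be >= 1")
    return max(0.3, 0.6 * math.sqrt(L - 0.5) - 2.5)


def tm_score(model: Structure, reference: Structure,
             corr: ResidueCorrespondence, atom: str = "C3'"
             ) -> tuple[float, float]:
    """TM-score over the fixed correspondence; returns (score, d0).

    Normalized by the reference RNA length L; the superposition search uses
    the same seed family as GDT, iterating inliers at d0 and d0/2 and keeping
    the superposition that maximizes the TM sum.
    """
    L = len(reference.rna_residues())
    if L < 1:
        raise ValueError("reference contains no RNA residues")
    d0 = tm_d0(L)
    pc = coordinates_for(model, reference, corr, atom)
    P, Q = pc.model_xyz, pc.reference_xyz

    def tm_of(d: np.ndarray) -> float:
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L)

    best = 0.0
    for sup in _seed_superpositions(P, Q):
        d = np.linalg.norm(sup.apply(P) - Q, axis=1)
        best = max(best, tm_of(d))
        for cutoff in (d0, max(d0 / 2.0, 0.5)):
            cur = sup
            prev_key = None
            for _ in range(12):
                d = np.linalg.norm(cur.apply(P) - Q, axis=1)
                best = max(best, tm_of(d))
                inliers = d <= cutoff
                key = inliers.tobytes()
                if inliers.sum() < 3 or key == prev_key:
                    break
                prev_key = key
                try:
                    cur = superpose(P[inliers], Q[inliers])
                except DegenerateInputError:
                    break
    return best, d0


# ---------------------------------------------------------------------------
# lDDT
# ---------------------------------------------------------------------------

def lddt_rna(model: Structure, reference: Structure,
             corr: ResidueCorrespondence,
             inclusion_radius: float = LDDT_INCLUSION_RADIUS,
             thresholds: Sequence[float] = LDDT_THRESHOLDS) -> float:
    """Local distance difference test, superposition-free, in [0, 1].

    Considers every heavy-atom pair in distinct residues whose reference
    distance is within the inclusion radius and whose atoms are both matched
    in the model; scores the mean, over the tolerance thresholds, of the
    fraction of pairs whose distance is preserved within the threshold.
    No stereochemical penalty is applied.
    """
    from scipy.spatial import cKDTree

    ref_xyz, mod_xyz, res_idx = [], [], []
    for i, j in corr.pairs:
        rm, rr = model.residues[i], reference.residues[j]
        for name in sorted(rm.atom_names() & rr.atom_names()):
            mod_xyz.append(rm.atom(name).position)
            ref_xyz.append(rr.atom(name).position)
            res_idx.append(j)
    if not ref_xyz:
        raise NoOverlapError("no matched atoms for lDDT")
    ref_xyz = np.asarray(ref_xyz)
    mod_xyz = np.asarray(mod_xyz)
    res_idx = np.asarray(res_idx)
    tree = cKDTree(ref_xyz)
    pairs = np.array(sorted(tree.query_pairs(inclusion_radius)))
    if len(pairs) == 0:
        raise NoOverlapError("no qualifying reference pairs for lDDT")
    distinct = res_idx[pairs[:, 0]] != res_idx[pairs[:, 1]]
    pairs = pairs[distinct]
    if len(pairs) == 0:
        raise NoOverlapError("no inter-residue reference pairs for lDDT")
    d_ref = np.linalg.norm(ref_xyz[pairs[:, 0]] - ref_xyz[pairs[:, 1]], axis=1)
    d_mod = np.linalg.norm(mod_xyz[pairs[:, 0]] - mod_xyz[pairs[:, 1]], axis=1)
    dev = np.abs(d_mod - d_ref)
    return float(np.mean([(dev <= t).mean() for t in thresholds]))


# ---------------------------------------------------------------------------
# INF family
# ---------------------------------------------------------------------------

def inf(reference_net: InteractionNetwork, model_net: InteractionNetwork,
        category: str = "ALL") -> float | None:
    """Interaction network fidelity: sqrt(PPV * sensitivity).

    With TP/FP/FN from the category-restricted edge sets; ``None`` when the
    reference category is empty (the score is undefined, not zero).
    """
    ref = reference_net.category(category)
    mod = model_net.category(category)
    if not ref:
        return None
    tp = len(ref & mod)
    fp = len(mod - ref)
    fn = len(ref - mod)
    if tp == 0:
        return 0.0
    return math.sqrt((tp / (tp + fp)) * (tp / (tp + fn)))


def deformation_index(rmsd: float, inf_all: float | None) -> float | None:
    """RMSD / INF; undefined (None) when INF is zero or undefined."""
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    if not inf_all:
        return None
    return rmsd / inf_all


# ---------------------------------------------------------------------------
# deformation profile
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DeformationProfile:
    """Per-nucleotide base RMSD matrix.

    Row i: superpose the model on the reference using residue i's heavy
    atoms; entry (i, j) is the base-atom RMSD of residue j under that
    superposition (no re-superposition).  Undefined rows are NaN.
    """

    matrix: np.ndarray  # (n, n), NaN where undefined
    residue_keys: list[str]

    @property
    def sum(self) -> float:
        return float(np.nansum(self.matrix))

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.matrix))

    @property
    def median(self) -> float:
        return float(np.nanmedian(self.matrix))


def _base_atom_names(res) -> list[str]:
    return [a.name for a in res.atoms if a.name not in BACKBONE_ATOMS]


def deformation_profile(model: Structure, reference: Structure,
                        corr: ResidueCorrespondence) -> DeformationProfile:
    """Anchor-wise base RMSD matrix localizing where a model deviates."""
    pairs = corr.pairs
    n = len(pairs)
    if n < 2:
        raise ValueError("deformation profile needs >= 2 corresponded residues")
    mat = np.full((n, n), np.nan)
    keys = [reference.residues[j].key for _, j in pairs]
    # matched atom coordinate cache per residue pair
    anchors, bases = [], []
    for i, j in pairs:
        rm, rr = model.residues[i], reference.residues[j]
        common = sorted(rm.atom_names() & rr.atom_names())
        a_m = np.array([rm.atom(nm).position for nm in common]) if common else np.empty((0, 3))
        a_r = np.array([rr.atom(nm).position for nm in common]) if common else np.empty((0, 3))
        anchors.append((a_m, a_r))
        bnames = sorted((set(_base_atom_names(rm)) & set(_base_atom_names(rr))))
        b_m = np.array([rm.atom(nm).position for nm in bnames]) if bnames else np.empty((0, 3))
        b_r = np.array([rr.atom(nm).position for nm in bnames]) if bnames else np.empty((0, 3))
        bases.append((b_m, b_r))
    for ai in range(n):
        a_m, a_r = anchors[ai]
        if len(a_m) < 3:
            continue  # row stays undefined
        try:
            sup = superpose(a_m, a_r)
        except DegenerateInputError:
            continue
        for bj in range(n):
            b_m, b_r = bases[bj]
            if len(b_m) == 0:
                continue
            diff = sup.apply(b_m) - b_r
            mat[ai, bj] = float(np.sqrt((diff ** 2).sum() / len(b_m)))
    return DeformationProfile(mat, keys)


# ---------------------------------------------------------------------------
# clashscore
# ---------------------------------------------------------------------------

def _bond_graph(structure: Structure) -> tuple[np.ndarray, list[list[int]]]:
    """Heavy-atom coordinates and covalent adjacency (distance-inferred).

    Bonds: intra-residue pairs closer than 1.8 Å plus the inter-residue
    O3'-P backbone linkage and the peptide C-N linkage.
    """
    xyz, owner, names = [], [], []
    for ri, res in enumerate(structure.residues):
        for a in res.atoms:
            xyz.append(a.position)
            owner.append(ri)
            names.append(a.name)
    xyz = np.asarray(xyz)
    adj: list[list[int]] = [[] for _ in range(len(xyz))]
    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    for i, j in tree.query_pairs(1.8):
        if owner[i] == owner[j]:
            adj[i].append(j)
            adj[j].append(i)
    # chain linkages (O3'-P, C-N) may exceed 1.8 in distorted models: catch
    # them with a slightly wider net between consecutive residues
    for i, j in tree.query_pairs(2.1):
        if owner[i] != owner[j]:
            ni, nj = names[i], names[j]
            if {ni, nj} in ({"O3'", "P"}, {"C", "N"}):
                adj[i].append(j)
                adj[j].append(i)
    return xyz, adj


def _within_bond_distance(adj, i, j, max_bonds=3) -> bool:
    """True when atoms are separated by at most ``max_bonds`` covalent bonds."""
    frontier = {i}
    seen = {i}
    for _ in range(max_bonds):
        nxt = set()
        for a in frontier:
            for b in adj[a]:
                if b == j:
                    return True
                if b not in seen:
                    seen.add(b)
                    nxt.add(b)
        frontier = nxt
        if not frontier:
            break
    return False


def clashscore(structure: Structure, per_residue: bool = False) -> float:
    """Steric clashes per 1000 heavy atoms (or per 1000 residues).

    A clash is an atom pair, separated by more than three covalent bonds,
    whose van-der-Waals spheres overlap by more than 0.4 Å.  Bonds are
    inferred from distances; no hydrogens are considered.
    """
    xyz, adj = _bond_graph(structure)
    names = [a.name for r in structure.residues for a in r.atoms]
    radii = np.array([VDW_RADII.get(n[0], 1.7) for n in names])
    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    max_d = 2 * radii.max() - CLASH_OVERLAP
    clashes = 0
    for i, j in tree.query_pairs(max_d):
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if radii[i] + radii[j] - d <= CLASH_OVERLAP:
            continue
        if _within_bond_distance(adj, i, j):
            continue
        clashes += 1
    denom = len(structure.residues) if per_residue else len(xyz)
    return 1000.0 * clashes / denom


# ---------------------------------------------------------------------------
# MCQ
# ---------------------------------------------------------------------------

def circular_distance(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def mcq(model_torsions: TorsionSet, reference_torsions: TorsionSet,
        corr: ResidueCorrespondence, model: Structure | None = None,
        reference: Structure | None = None,
        key_pairs: list[tuple[str, str]] | None = None) -> float:
    """Mean of circular quantities over torsions defined in both structures.

    ``key_pairs`` gives (model residue key, reference residue key) pairs; when
    omitted, the structures must be supplied so the keys can be derived from
    the correspondence.
    """
    if key_pairs is None:
        if model is None or reference is None:
            raise ValueError("need structures or explicit key pairs")
        key_pairs = [(model.residues[i].key, reference.residues[j].key)
                     for i, j in corr.pairs]
    dists = []
    for mk, rk in key_pairs:
        ma = model_torsions.angles.get(mk)
        ra = reference_torsions.angles.get(rk)
        if ma is None or ra is None:
            continue
        for name, mv in ma.items():
            rv = ra.get(name)
            if mv is None or rv is None:
                continue
            dists.append(circular_distance(mv, rv))
    if not dists:
        raise NoOverlapError("no shared defined torsions for MCQ")
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MetricReport:
    """All per-model scores for one model/reference comparison."""

    rmsd: float
    gdt_ts: float
    tm_score: float
    d0: float
    lddt: float
    inf_all: float | None
    inf_wc: float | None
    inf_nwc: float | None
    inf_bps: float | None
    inf_stack: float | None
    di: float | None
    clashscore: float
    clashscore_per_residue: float
    mcq: float | None

    def as_dict(self) -> dict[str, float | None]:
        return dataclasses.asdict(self)


def compute_report(model: Structure, reference: Structure,
                   corr: ResidueCorrespondence) -> MetricReport:
    """Compute the full metric set for one model against one reference."""
    rmsd = rmsd_heavy(model, reference, corr)
    gdt = gdt_ts(model, reference, corr)
    tm, d0 = tm_score(model, reference, corr)
    lddt = lddt_rna(model, reference, corr)
    # networks are keyed on reference residue keys so edges are comparable:
    # relabel model residues via the correspondence
    ref_net = annotate(reference)
    mod_net = annotate(model)
    relabel = {model.residues[i].key: reference.residues[j].key
               for i, j in corr.pairs}
    mod_net = InteractionNetwork(
        wc={frozenset(relabel[k] for k in e) for e in mod_net.wc
            if all(k in relabel for k in e)},
        nwc={frozenset(relabel[k] for k in e) for e in mod_net.nwc
             if all(k in relabel for k in e)},
        stack={frozenset(relabel[k] for k in e) for e in mod_net.stack
               if all(k in relabel for k in e)},
    )
    inf_all = inf(ref_net, mod_net, "ALL")
    report = MetricReport(
        rmsd=rmsd, gdt_ts=gdt, tm_score=tm, d0=d0, lddt=lddt,
        inf_all=inf_all,
        inf_wc=inf(ref_net, mod_net, "WC"),
        inf_nwc=inf(ref_net, mod_net, "NWC"),
        inf_bps=inf(ref_net, mod_net, "BPS"),
        inf_stack=inf(ref_net, mod_net, "STACK"),
        di=deformation_index(rmsd, inf_all),
        clashscore=clashscore(model),
        clashscore_per_residue=clashscore(model, per_residue=True),
        mcq=None,
    )
    try:
        report.mcq = mcq(compute_torsions(model), compute_torsions(reference),
                         corr, model, reference)
    except NoOverlapError:
        pass
    return report
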