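"""Synthetic fixtures: idealized A-form duplexes with known pairing,
controlled decoys and simulated score tables.

The duplex generator produces analytic, clash-free double helices whose
Watson-Crick pairing (including G·U wobbles) and stacking lists are known by
construction, so annotation and every structure metric can be validated
without external data.  Geometry is built from the standard base reference
frame (planar heavy-atom coordinates for A, C, G, U) mounted on an idealized
helical sugar-phosphate backbone: the backbone template was solved once, by
least squares over bond-geometry constraints plus the requirement that the
helix symmetry operation carries each O3' onto the next residue's P, and is
hard-coded below.  G·U wobble pairs are realized by in-plane rotations of the
two bases about their glycosidic attachment points (angles solved once,
hard-coded) because the rigid helical backbone cannot absorb the canonical
wobble shear.
"""
from __future__ import annotations

import dataclasses
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import InteractionNetwork
from .ranking import ORIENTATION, ScoreTable
from .structure_io import Atom, Residue, Structure

__all__ = [
    "HelixSpec",
    "DecoySpec",
    "build_duplex",
    "make_decoy",
    "simulate_score_table",
    "WC_COMPLEMENT",
    "METRIC_BASELINES",
]

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_ALLOWED_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}

# ---------------------------------------------------------------------------
# geometry constants (see module docstring for provenance)
# ---------------------------------------------------------------------------

# planar heavy-atom base templates, standard reference frame (x, y; z = 0)
BASE_TEMPLATES: dict[str, dict[str, tuple[float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
        "C5": (0.071, 2.771), "C6": (0.369, 1.398), "N6": (1.611, 0.909),
        "N1": (-0.668, 0.532), "C2": (-1.912, 1.023), "N3": (-2.320, 2.290),
        "C4": (-1.267, 3.124), "C1'": (-2.479, 5.346),
    },
    "G": {
        "N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
        "C5": (0.071, 2.833), "C6": (0.424, 1.460), "O6": (1.554, 0.955),
        "N1": (-0.700, 0.641), "C2": (-1.999, 1.087), "N2": (-2.949, 0.139),
        "N3": (-2.342, 2.364), "C4": (-1.265, 3.177), "C1'": (-2.477, 5.399),
    },
    "C": {
        "N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "O2": (-2.628, 2.709),
        "N3": (-0.391, 2.344), "C4": (0.837, 2.868), "N4": (1.875, 2.027),
        "C5": (1.056, 4.275), "C6": (-0.023, 5.068), "C1'": (-2.477, 5.402),
    },
    "U": {
        "N1": (-1.284, 4.500), "C2": (-1.462, 3.131), "O2": (-2.563, 2.608),
        "N3": (-0.302, 2.397), "C4": (0.989, 2.884), "O4": (1.935, 2.094),
        "C5": (1.089, 4.311), "C6": (-0.024, 5.053), "C1'": (-2.491, 5.362),
    },
}

# canonical C1' attachment point in the (pre-tilt) pair frame
C1_ATTACH = np.array([-2.48, 5.37, 0.0])

# sugar-phosphate template in the (pre-tilt) pair frame (solved once by
# constrained least squares; see module docstring)
BACKBONE_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "C1'": (-2.4800, 5.3700, 0.0000),
    "O4'": (-2.7208, 6.7795, 0.3809),
    "C2'": (-3.9682, 5.1650, -0.4420),
    "O2'": (-3.9726, 4.9959, -1.8418),
    "C3'": (-4.8571, 6.3557, -0.0730),
    "O3'": (-5.7400, 6.0531, 0.9842),
    "C4'": (-3.9796, 7.5812, 0.2864),
    "C5'": (-3.9746, 8.5026, -0.9044),
    "O5'": (-2.7478, 9.1771, -1.1994),
    "P": (-1.6006, 8.4599, -2.0306),
    "OP1": (-0.3383, 8.5710, -1.2569),
    "OP2": (-1.9878, 7.0812, -2.4081),
}

# in-plane wobble rotations (degrees) applied to G and U bases of G·U pairs
WOBBLE_ROTATION = {"G": -15.3882, "U": 10.9289}

ATOM_ORDER_BACKBONE = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
                       "C3'", "O3'", "C2'", "O2'", "C1'"]


@dataclasses.dataclass
class HelixSpec:
    """Specification of an idealized duplex.

    ``sequence`` is strand 1 (5'->3'); ``strand2`` defaults to its reverse
    Watson-Crick complement and may be overridden to introduce G·U wobbles
    (each opposing pair must be AU, GC or GU).  Twist/rise are per base pair;
    ``inclination`` tilts the pair plane against the helix axis and
    ``x_displacement`` shifts the pair away from the axis, the combination
    giving clash-free stacking at the A-form rise.
    """

    sequence: str
    strand2: str | None = None
    twist: float = 32.7          # degrees per bp
    rise: float = 2.81           # Å per bp
    inclination: float = 20.0    # degrees
    x_displacement: float = -4.4  # Å

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("T", "U")
        if not self.sequence or set(self.sequence) - set("ACGU"):
            raise ValueError("sequence must be non-empty over {A, C, G, U}")
        if not 0 < self.twist < 360:
            raise ValueError("twist must be in (0, 360)")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.strand2 is None:
            self.strand2 = "".join(WC_COMPLEMENT[b]
                                   for b in reversed(self.sequence))
        else:
            self.strand2 = self.strand2.upper().replace("T", "U")
            if len(self.strand2) != len(self.sequence):
                raise ValueError("strand2 length must match sequence")
            for b1, b2 in zip(self.sequence, reversed(self.strand2)):
                if b1 + b2 not in _ALLOWED_PAIRS:
                    raise ValueError(f"cannot pair {b1} with {b2}")


def _rz(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rx(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


_FLIP = np.diag([1.0, -1.0, -1.0])  # duplex dyad (rotation about x)


def _base_atoms(code: str, wobble_deg: float = 0.0) -> dict[str, np.ndarray]:
    """Base heavy atoms in the pair frame, C1' placed at the canonical
    attachment point, optionally rotated in-plane about C1'."""
    tab = BASE_TEMPLATES[code]
    c1 = np.array([*tab["C1'"], 0.0])
    R = _rz(wobble_deg)
    return {n: R @ (np.array([*xy, 0.0]) - c1) + C1_ATTACH
            for n, xy in tab.items() if n != "C1'"}


def _residue_template(code: str, wobble_deg: float) -> dict[str, np.ndarray]:
    atoms = {n: np.array(p) for n, p in BACKBONE_TEMPLATE.items()}
    atoms.update(_base_atoms(code, wobble_deg))
    return atoms


def build_duplex(spec: HelixSpec | str
                 ) -> tuple[Structure, InteractionNetwork]:
    """Build an idealized duplex and its designed interaction network.

    Returns the structure (chains A and B, residues numbered 1..n in each
    strand's 5'->3' direction) together with the ground-truth network: one WC
    pair per base-pair level and the intra-strand stacking list.  The
    structure is clash-free under the clashscore operation.
    """
    if isinstance(spec, str):
        spec = HelixSpec(spec)
    n = len(spec.sequence)
    tilt = _rx(spec.inclination)
    off = np.array([spec.x_displacement, 0.0, 0.0])
    s2_rev = spec.strand2[::-1]  # s2_rev[k] pairs sequence[k] at level k

    residues: list[Residue] = []
    # strand 1: chain A, residue i (1-based) at level i-1
    for i, code in enumerate(spec.sequence):
        partner = s2_rev[i]
        wob = {code, partner} == {"G", "U"}
        tpl = _residue_template(code, WOBBLE_ROTATION[code] if wob else 0.0)
        Rk = _rz(spec.twist * i)
        lift = np.array([0.0, 0.0, spec.rise * i])
        atoms = []
        for name in ATOM_ORDER_BACKBONE + sorted(
                set(tpl) - set(ATOM_ORDER_BACKBONE)):
            if i == 0 and name in ("P", "OP1", "OP2"):
                continue  # 5' terminus carries no phosphate
            p = Rk @ (tilt @ tpl[name] + off) + lift
            atoms.append(Atom(name, name[0], p))
        residues.append(Residue("A", i + 1, code, atoms, kind="rna",
                                parent=code))
    # strand 2: chain B, residue j (1-based, its own 5'->3') at level n-j
    for j, code in enumerate(spec.strand2):
        level = n - 1 - j
        partner = spec.sequence[level]
        wob = {code, partner} == {"G", "U"}
        tpl = _residue_template(code, WOBBLE_ROTATION[code] if wob else 0.0)
        Rk = _rz(spec.twist * level)
        lift = np.array([0.0, 0.0, spec.rise * level])
        atoms = []
        for name in ATOM_ORDER_BACKBONE + sorted(
                set(tpl) - set(ATOM_ORDER_BACKBONE)):
            if j == 0 and name in ("P", "OP1", "OP2"):
                continue
            p = Rk @ (tilt @ (_FLIP @ tpl[name]) + off) + lift
            atoms.append(Atom(name, name[0], p))
        residues.append(Residue("B", j + 1, code, atoms, kind="rna",
                                parent=code))

    st = Structure(id=f"duplex-{spec.sequence}", residues=residues)

    truth = InteractionNetwork()
    for i in range(n):
        truth.wc.add(frozenset((f"A:{i + 1}", f"B:{n - i}")))
    for i in range(n - 1):
        truth.stack.add(frozenset((f"A:{i + 1}", f"A:{i + 2}")))
        truth.stack.add(frozenset((f"B:{i + 1}", f"B:{i + 2}")))
    return st, truth


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DecoySpec:
    """Deterministic perturbation of a base structure.

    kinds: ``gaussian`` (i.i.d. per-coordinate noise, scaled by sigma so one
    seed yields a nested family across sigmas), ``hinge`` (rotate all
    residues after the pivot about the backbone bond axis), ``rigid`` (global
    rotation + translation), ``register`` (shift residue numbering by k).
    """

    kind: Literal["gaussian", "hinge", "rigid", "register"]
    sigma: float = 0.0
    pivot: int = 0               # residue index within the structure (hinge)
    angle: float = 0.0           # degrees (hinge / rigid about axis)
    axis: Sequence[float] = (0.0, 0.0, 1.0)   # rigid rotation axis
    translation: Sequence[float] = (0.0, 0.0, 0.0)
    shift: int = 0               # register shift in residue numbering
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def _copy_structure(st: Structure, suffix: str) -> Structure:
    return Structure(
        id=f"{st.id}-{suffix}",
        residues=[Residue(r.chain_id, r.seq_id, r.res_name,
                          [Atom(a.name, a.element, a.position.copy())
                           for a in r.atoms],
                          r.insertion_code, r.kind, r.parent)
                  for r in st.residues])


def _rotation_about(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def make_decoy(base: Structure, spec: DecoySpec) -> Structure:
    """Apply a deterministic perturbation; identical seeds give identical
    structures."""
    out = _copy_structure(base, spec.kind)
    if spec.kind == "gaussian":
        rng = np.random.default_rng(spec.seed)
        for r in out.residues:
            for a in r.atoms:
                a.position = a.position + spec.sigma * rng.standard_normal(3)
    elif spec.kind == "rigid":
        R = _rotation_about(np.asarray(spec.axis), spec.angle)
        t = np.asarray(spec.translation, dtype=float)
        for r in out.residues:
            for a in r.atoms:
                a.position = R @ a.position + t
    elif spec.kind == "hinge":
        if not 0 <= spec.pivot < len(out.residues) - 1:
            raise ValueError("hinge pivot outside the chain")
        piv = out.residues[spec.pivot]
        nxt = out.residues[spec.pivot + 1]
        if piv.chain_id != nxt.chain_id:
            raise ValueError("hinge pivot must not be a chain terminus")
        o3 = piv.atom("O3'")
        p = nxt.atom("P") or nxt.atom("O5'")
        if o3 is None or p is None:
            raise ValueError("hinge pivot lacks backbone linkage atoms")
        origin = o3.position
        R = _rotation_about(p.position - origin, spec.angle)
        for r in out.residues[spec.pivot + 1:]:
            if r.chain_id != piv.chain_id:
                break
            for a in r.atoms:
                a.position = R @ (a.position - origin) + origin
    elif spec.kind == "register":
        for r in out.residues:
            r.seq_id += spec.shift
    else:
        raise ValueError(f"unknown decoy kind {spec.kind!r}")
    return out


# ---------------------------------------------------------------------------
# simulated score tables
# ---------------------------------------------------------------------------

# plausible central values per metric for a mid-quality prediction
METRIC_BASELINES: dict[str, float] = {
    "tm_score": 0.6, "gdt_ts": 50.0, "lddt": 0.7, "inf_all": 0.7,
    "clashscore": 20.0, "rmsd": 8.0,
}


def simulate_score_table(n_targets: int, n_groups: int,
                         group_effects: Sequence[float] | None = None,
                         noise_sd: float = 1.0, missing_rate: float = 0.0,
                         seed: int = 0, n_models: int = 5,
                         metrics: Mapping[str, float] = METRIC_BASELINES,
                         ) -> ScoreTable:
    """Simulate a long-format score table with planted group quality.

    Each value is ``baseline ± (group effect + N(0, noise_sd))`` with the
    sign chosen so a larger effect always means a better score under the
    metric's orientation.  A ``missing_rate`` fraction of (group, target)
    cells is dropped entirely.  Deterministic for a fixed seed.
    """
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if group_effects is None:
        group_effects = np.zeros(n_groups)
    group_effects = np.asarray(group_effects, dtype=float)
    if len(group_effects) != n_groups:
        raise ValueError("group_effects length must equal n_groups")
    rng = np.random.default_rng(seed)
    targets = [f"T{t + 1:02d}" for t in range(n_targets)]
    groups = [f"G{g + 1:03d}" for g in range(n_groups)]
    metric_names = list(metrics)
    signs = np.array([1.0 if ORIENTATION[m] else -1.0 for m in metric_names])
    baselines = np.array([metrics[m] for m in metric_names])
    keep = np.ones((n_targets, n_groups), dtype=bool)
    if missing_rate > 0:
        keep = rng.random((n_targets, n_groups)) >= missing_rate
    noise = rng.normal(0.0, noise_sd,
                       (n_targets, n_groups, n_models, len(metric_names)))
    values = baselines + signs * (group_effects[None, :, None, None] + noise)
    ti, gi, mi, ki = np.nonzero(
        keep[:, :, None, None] & np.ones_like(values, dtype=bool))
    frame = pd.DataFrame({
        "target": np.array(targets)[ti],
        "group": np.array(groups)[gi],
        "model": mi + 1,
        "conformation": "C1",
        "metric": np.array(metric_names)[ki],
        "value": values[ti, gi, mi, ki],
    })
    return ScoreTable(frame)
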