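"""Two-pass Z-score aggregation and group ranking.

Implements the CASP-style ranking scheme: per target and metric, each group
is represented by its best model over all submitted models and all reference
conformations; Z-scores are standardized across groups in two passes (models
whose first-pass Z falls below a tolerance are discarded before recomputing
the statistics, and final scores are floored at a clip value); weighted
combinations of component Z-scores are summed, and groups are ranked by the
sum of positive combined Z over targets.  A podium (3/2/1 weighted placement
count) ranking is provided as the complementary scheme.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ORIENTATION",
    "ScoreTable",
    "ZConfig",
    "Z_RNA",
    "Z_EM",
    "Z_MX",
    "RankingResult",
    "PodiumCounts",
    "best_of_group",
    "two_pass_z",
    "combine_z",
    "rank_groups",
    "podium_ranking",
]

# higher-is-better flag per metric name
ORIENTATION: dict[str, bool] = {
    "tm_score": True, "gdt_ts": True, "lddt": True,
    "inf_all": True, "inf_wc": True, "inf_nwc": True, "inf_bps": True,
    "inf_stack": True,
    "rmsd": False, "di": False, "clashscore": False,
    "clashscore_per_residue": False, "mcq": False,
    "dp_sum": False, "dp_mean": False, "dp_median": False,
    # map-to-model metrics (values supplied externally)
    "cc_mask": True, "cc_peaks": True, "mi": True, "smoc": True,
    "atomic_inclusion": True,
    # crystallographic metrics (values supplied externally)
    "llg": True, "tfz": True, "map_cc": True,
}

_COLUMNS = ["target", "group", "model", "conformation", "metric", "value"]


@dataclasses.dataclass
class ScoreTable:
    """Long-format per-model score records.

    One row per (target, group, model index, reference conformation, metric);
    metric orientation comes from a registry that can be extended for
    externally computed metrics.
    """

    frame: pd.DataFrame
    orientation: dict[str, bool] = dataclasses.field(
        default_factory=lambda: dict(ORIENTATION))

    def __post_init__(self):
        missing = [c for c in _COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"score table missing columns: {missing}")
        dup = self.frame.duplicated(subset=_COLUMNS[:-1])
        if dup.any():
            raise ValueError("duplicate (target, group, model, conformation, "
                             "metric) records")

    def higher_better(self, metric: str) -> bool:
        try:
            return self.orientation[metric]
        except KeyError:
            raise KeyError(f"metric {metric!r} has no registered orientation")

    @property
    def targets(self) -> list[str]:
        return sorted(self.frame["target"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    @property
    def metrics(self) -> list[str]:
        return sorted(self.frame["metric"].unique())

    def filter_rmsd(self, max_rmsd: Mapping[str, float]) -> "ScoreTable":
        """Drop (target, group, model, conformation) entries whose RMSD
        exceeds a per-target threshold (used before map-based rankings)."""
        f = self.frame
        bad_keys = set()
        for tgt, thr in max_rmsd.items():
            sel = (f["target"] == tgt) & (f["metric"] == "rmsd") & (f["value"] > thr)
            for _, row in f[sel].iterrows():
                bad_keys.add((row["target"], row["group"], row["model"],
                              row["conformation"]))
        keep = ~f.apply(lambda r: (r["target"], r["group"], r["model"],
                                   r["conformation"]) in bad_keys, axis=1)
        return ScoreTable(f[keep].reset_index(drop=True), dict(self.orientation))

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["value"] = out["value"].map(lambda v: f"{v:.4f}")
        out.sort_values(_COLUMNS[:-1]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 orientation: Mapping[str, bool] | None = None) -> "ScoreTable":
        f = pd.read_csv(path)
        f["value"] = f["value"].astype(float)
        ori = dict(ORIENTATION)
        if orientation:
            ori.update(orientation)
        return cls(f, ori)


@dataclasses.dataclass
class ZConfig:
    """Weights and thresholds for a weighted Z-score combination."""

    weights: dict[str, float]
    tolerance: float = -2.0  # pass-1 discard threshold
    clip: float = -2.0       # post-pass-2 floor

    def __post_init__(self):
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("component weights must be positive")


Z_RNA = ZConfig({"tm_score": 1 / 3, "gdt_ts": 1 / 3,
                 "inf_all": 1 / 8, "lddt": 1 / 8, "clashscore": 1 / 12})
Z_EM = ZConfig({m: 1 / 5 for m in
                ("cc_mask", "cc_peaks", "mi", "smoc", "atomic_inclusion")})
Z_MX = ZConfig({m: 1 / 3 for m in ("llg", "tfz", "map_cc")})


def best_of_group(table: ScoreTable, target: str, group: str,
                  metric: str) -> float:
    """Best value over a group's models and all reference conformations.

    Respects metric orientation (max for higher-better, min for lower-better);
    NaN when the group has no record for the target/metric.
    """
    f = table.frame
    sel = f[(f["target"] == target) & (f["group"] == group)
            & (f["metric"] == metric)]
    vals = sel["value"].dropna()
    if vals.empty:
        return float("nan")
    return float(vals.max() if table.higher_better(metric) else vals.min())


def two_pass_z(values: Mapping[str, float], higher_better: bool = True,
               tolerance: float = -2.0, clip: float = -2.0
               ) -> dict[str, float]:
    """Two-pass Z-scores across groups.

    Pass 1 standardizes over all finite values (population standard
    deviation); groups below the tolerance are discarded; pass 2 recomputes
    mean/sd on the kept set and re-scores *all* groups against those
    statistics.  Scores below the clip, and missing values, become the clip.
    """
    keys = list(values)
    if len(keys) < 2:
        raise ValueError("need at least two groups for Z-scores")
    sign = 1.0 if higher_better else -1.0
    v = np.array([values[k] for k in keys], dtype=float) * sign
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise ValueError("need at least two finite values for Z-scores")

    def zpass(mask):
        mean = v[mask].mean()
        sd = v[mask].std()  # population sd
        if sd == 0:
            return np.zeros_like(v)
        return (v - mean) / sd

    z1 = zpass(finite)
    kept = finite & (z1 >= tolerance)
    if kept.sum() < 2:
        kept = finite
    z2 = zpass(kept)
    out = {}
    for k, zi, ok in zip(keys, z2, finite):
        out[k] = float(max(zi, clip)) if ok else clip
    return out


def combine_z(component_z: Mapping[str, float], config: ZConfig) -> float:
    """Weighted sum of component Z-scores; missing components contribute the
    clip value."""
    total = 0.0
    for metric, w in config.weights.items():
        z = component_z.get(metric)
        if z is None or not math.isfinite(z):
            z = config.clip
        total += w * z
    return total


@dataclasses.dataclass
class RankingResult:
    """Per-group combined Z-scores, positive-Z totals and final ordering."""

    per_target: pd.DataFrame    # index: group, columns: target -> combined Z
    component_z: pd.DataFrame   # long: target, group, metric, z
    totals: pd.Series           # group -> sum of positive combined Z
    ranks: pd.Series            # group -> 1-based rank

    @property
    def ordering(self) -> list[str]:
        return list(self.ranks.sort_values().index)

    def leaderboard(self) -> pd.DataFrame:
        board = pd.DataFrame({
            "rank": self.ranks,
            "positive_z_sum": self.totals,
        })
        comp = self.component_z.pivot_table(index="group", columns="metric",
                                            values="z", aggfunc="sum")
        comp.columns = [f"z_{c}_sum" for c in comp.columns]
        return board.join(comp).sort_values("rank")


def rank_groups(table: ScoreTable, config: ZConfig) -> RankingResult:
    """Rank groups by the sum of positive combined Z-scores over targets.

    Per target: best-of-group per metric, two-pass Z across groups per
    metric, weighted combination; a group missing a target contributes zero
    (never negative) to its total.  Ties are broken by the unclipped total of
    combined Z, then by group id.
    """
    targets = table.targets
    groups = table.groups
    if len(groups) < 2 or not targets:
        raise ValueError("ranking needs >= 2 groups and >= 1 target")
    metrics = [m for m in config.weights if m in set(table.metrics)]
    if not metrics:
        raise ValueError("no config metric present in the score table")
    # vectorized best-of-group per (target, group, metric)
    f = table.frame
    best = {}
    for metric in metrics:
        sub = f[f["metric"] == metric]
        agg = "max" if table.higher_better(metric) else "min"
        best[metric] = (sub.groupby(["target", "group"])["value"]
                        .agg(agg).unstack("group")
                        .reindex(index=targets, columns=groups))
    comp_rows = []
    combined = pd.DataFrame(index=groups, columns=targets, dtype=float)
    for tgt in targets:
        zs: dict[str, dict[str, float]] = {}
        for metric in metrics:
            vals = best[metric].loc[tgt].to_dict()
            zmap = two_pass_z(vals, table.higher_better(metric),
                              config.tolerance, config.clip)
            zs[metric] = zmap
            for g, z in zmap.items():
                comp_rows.append({"target": tgt, "group": g,
                                  "metric": metric, "z": z})
        for g in groups:
            combined.loc[g, tgt] = combine_z(
                {m: zs[m][g] for m in metrics}, config)
    totals = combined.clip(lower=0.0).sum(axis=1)
    unclipped = combined.sum(axis=1)
    order = sorted(groups, key=lambda g: (-totals[g], -unclipped[g], g))
    ranks = pd.Series({g: i + 1 for i, g in enumerate(order)}, name="rank")
    return RankingResult(per_target=combined,
                         component_z=pd.DataFrame(comp_rows),
                         totals=totals, ranks=ranks.loc[groups])


# ---------------------------------------------------------------------------
# podium ranking
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PodiumCounts:
    """1st/2nd/3rd placement counts per group with 3/2/1 weighting."""

    counts: pd.DataFrame  # index: group, columns: first, second, third

    @property
    def weighted(self) -> pd.Series:
        c = self.counts
        return 3 * c["first"] + 2 * c["second"] + 1 * c["third"]

    @property
    def ordering(self) -> list[str]:
        w = self.weighted
        return list(w.sort_values(ascending=False, kind="stable").index)


def podium_ranking(table: ScoreTable, metrics: Sequence[str] | None = None,
                   scope: str = "best_of_5") -> PodiumCounts:
    """Count podium placements (1st/2nd/3rd) per group over targets and
    metrics.

    ``scope`` is ``best_of_5`` (all submitted models count) or
    ``model_1_only``.  Tied groups share the better placement and consume the
    following one(s).
    """
    if scope not in ("best_of_5", "model_1_only"):
        raise ValueError(f"unknown scope {scope!r}")
    f = table.frame
    if scope == "model_1_only":
        f = f[f["model"] == 1]
        table = ScoreTable(f.reset_index(drop=True), dict(table.orientation))
    groups = table.groups
    if len(groups) < 3:
        raise ValueError("podium ranking needs >= 3 groups")
    if metrics is None:
        metrics = table.metrics
    from scipy.stats import rankdata

    counts = pd.DataFrame(0, index=groups,
                          columns=["first", "second", "third"])
    for tgt in table.targets:
        for metric in metrics:
            vals = {g: best_of_group(table, tgt, g, metric) for g in groups}
            present = [g for g in groups if math.isfinite(vals[g])]
            if len(present) < 1:
                continue
            v = np.array([vals[g] for g in present])
            if table.higher_better(metric):
                v = -v
            ranks = rankdata(v, method="min")  # ties share the better place
            for g, r in zip(present, ranks):
                if r == 1:
                    counts.loc[g, "first"] += 1
                elif r == 2:
                    counts.loc[g, "second"] += 1
                elif r == 3:
                    counts.loc[g, "third"] += 1
    return PodiumCounts(counts)
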