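"""End-to-end orchestration: score a directory of predictor models against
all reference conformations of a target and build score tables.

Model files follow the CASP convention ``<target>TS<group>_<idx>`` (a
manifest CSV can map arbitrary filenames instead).  Individual model
failures are logged and recorded, never aborting the batch; reruns with the
same inputs produce byte-identical CSV output.
"""
from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .annotation import AnnotationThresholds
from .metrics import compute_report
from .ranking import ORIENTATION, ScoreTable, ZConfig, Z_RNA
from .structure_io import (Ensemble, StructureError, build_correspondence,
                           read_structure)

__all__ = ["AssessmentConfig", "assess_target", "parse_model_filename"]

logger = logging.getLogger("rna_assess")

_MODEL_RE = re.compile(r"^(?P<target>[A-Za-z0-9]+?)TS(?P<group>\d+)_(?P<idx>\d+)$")

# metric fields of a report included in score tables by default
DEFAULT_METRICS = ("rmsd", "gdt_ts", "tm_score", "lddt", "inf_all", "inf_wc",
                   "inf_nwc", "inf_bps", "inf_stack", "di", "clashscore",
                   "mcq")


@dataclasses.dataclass
class AssessmentConfig:
    """Configuration of one assessment run; defaults follow the assessment
    protocol (C4' GDT, C3' TM-score, 15 Å lDDT radius, 5 Å contacts, Z
    tolerance/clip -2, global-fold-weighted combination)."""

    correspondence: str = "by_numbering"
    metrics: tuple[str, ...] = DEFAULT_METRICS
    zconfig: ZConfig = dataclasses.field(
        default_factory=lambda: ZConfig(dict(Z_RNA.weights)))
    clash_per_residue: bool = False
    annotation: AnnotationThresholds = dataclasses.field(
        default_factory=AnnotationThresholds)
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "correspondence": self.correspondence,
            "metrics": list(self.metrics),
            "z_weights": self.zconfig.weights,
            "z_tolerance": self.zconfig.tolerance,
            "z_clip": self.zconfig.clip,
            "clash_per_residue": self.clash_per_residue,
            "annotation": dataclasses.asdict(self.annotation),
            "log_level": self.log_level,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssessmentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "correspondence" in data:
            cfg.correspondence = data["correspondence"]
        if "metrics" in data:
            cfg.metrics = tuple(data["metrics"])
        if "z_weights" in data:
            cfg.zconfig = ZConfig(dict(data["z_weights"]),
                                  data.get("z_tolerance", -2.0),
                                  data.get("z_clip", -2.0))
        if "clash_per_residue" in data:
            cfg.clash_per_residue = bool(data["clash_per_residue"])
        if "annotation" in data:
            ann = data["annotation"]
            for k, v in ann.items():
                setattr(cfg.annotation, k,
                        tuple(v) if isinstance(v, list) else v)
        if "log_level" in data:
            cfg.log_level = data["log_level"]
        return cfg


def parse_model_filename(path: str | Path) -> tuple[str, str, int] | None:
    """Parse ``<target>TS<group>_<idx>`` from a filename stem."""
    m = _MODEL_RE.match(Path(path).stem)
    if not m:
        return None
    return m.group("target"), m.group("group"), int(m.group("idx"))


def _iter_models(models: str | Path | Iterable[str | Path],
                 manifest: str | Path | None):
    if manifest is not None:
        table = pd.read_csv(manifest)
        for _, row in table.iterrows():
            yield Path(row["path"]), str(row["group"]), int(row["model"])
        return
    if isinstance(models, (str, Path)):
        paths = sorted(Path(models).iterdir())
    else:
        paths = [Path(p) for p in models]
    for p in paths:
        if p.suffix.lower() not in (".pdb", ".cif", ".mmcif", ".ent"):
            continue
        parsed = parse_model_filename(p)
        if parsed is None:
            logger.warning("cannot parse model filename %s; skipped", p.name)
            continue
        _, group, idx = parsed
        yield p, group, idx


def assess_target(models: str | Path | Iterable[str | Path],
                  references: Ensemble,
                  config: AssessmentConfig | None = None,
                  manifest: str | Path | None = None,
                  ) -> tuple[ScoreTable, list[dict]]:
    """Score every model against every reference conformation.

    Returns the score table plus a list of failure records
    ``{"path", "group", "model", "reason"}`` for models that could not be
    scored; a corrupt model never aborts the batch.
    """
    config = config or AssessmentConfig()
    target = references.label
    rows = []
    failures: list[dict] = []
    for path, group, idx in _iter_models(models, manifest):
        try:
            ens = read_structure(path)
            model = ens.members[0]
        except StructureError as exc:
            logger.error("model %s unreadable: %s", path, exc)
            failures.append({"path": str(path), "group": group,
                             "model": idx, "reason": str(exc)})
            continue
        for c_i, ref in enumerate(references.members, start=1):
            conf = f"C{c_i}"
            try:
                corr = build_correspondence(model, ref, config.correspondence)
                report = compute_report(model, ref, corr)
            except (StructureError, ValueError) as exc:
                logger.error("scoring %s vs %s failed: %s", path, conf, exc)
                failures.append({"path": str(path), "group": group,
                                 "model": idx, "reason": f"{conf}: {exc}"})
                continue
            d = report.as_dict()
            if config.clash_per_residue:
                d["clashscore"] = d["clashscore_per_residue"]
            for metric in config.metrics:
                value = d.get(metric)
                if value is None:
                    continue
                rows.append((target, group, idx, conf, metric, float(value)))
    frame = pd.DataFrame(rows, columns=["target", "group", "model",
                                        "conformation", "metric", "value"])
    frame = frame.sort_values(list(frame.columns[:5])).reset_index(drop=True)
    return ScoreTable(frame), failures
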