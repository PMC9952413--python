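"""End-to-end pipeline: dataset filter -> features -> classify -> select
-> regress -> cluster -> group assignment, with per-stage artifacts."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset, features as feat, statpipe, structio, surface
from .errors import ProsfoldError

log = logging.getLogger("prosfold")


@dataclass
class RunConfig:
    segment_table: str
    output_dir: str
    structure_dir: str | None = None  # base for relative exp/model paths
    alpha: float = statpipe.DEFAULT_ALPHA
    boundaries: tuple[float, float] | None = statpipe.DEFAULT_BOUNDARIES
    # boundaries=None -> optimize from the data ("auto")
    outlier_threshold: float = statpipe.DEFAULT_OUTLIER_THRESHOLD
    sasa_points: int = surface.N_SPHERE_POINTS
    seed: int = 0
    skip_interaction_filter: bool = False
    feature_subset: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not Path(self.segment_table).exists():
            raise ProsfoldError(f"segment table not found: {self.segment_table}")
        if self.boundaries is not None and not self.boundaries[0] < self.boundaries[1]:
            raise ProsfoldError(f"boundaries must increase: {self.boundaries}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if raw.get("boundaries") == "auto":
            raw["boundaries"] = None
        elif isinstance(raw.get("boundaries"), list):
            raw["boundaries"] = tuple(raw["boundaries"])
        return cls(**raw)


def _resolve(path: str, base: str | None) -> Path:
    p = Path(path)
    if not p.is_absolute() and base:
        p = Path(base) / p
    return p


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages; returns a dict of artifact paths.

    A segment that fails at any per-segment stage is skipped with the
    reason logged; the run only aborts when the final dataset is empty.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    records = structio.read_segment_table(config.segment_table)
    log.info("loaded %d segment records", len(records))

    cache: dict[str, structio.Structure] = {}

    def load(path: str) -> structio.Structure:
        resolved = str(_resolve(path, config.structure_dir))
        if resolved not in cache:
            cache[resolved] = structio.read_structure(resolved)
        return cache[resolved]

    loader = None if config.skip_interaction_filter else load
    report = dataset.filter_segments(records, loader, sasa_points=config.sasa_points)
    artifacts["dataset_report"] = out / "dataset_report.json"
    artifacts["dataset_report"].write_text(json.dumps(report.to_dict(), indent=1))
    log.info("dataset filter kept %d/%d records", len(report.final_records), len(records))
    if not report.final_records:
        raise ProsfoldError("empty dataset after filtering")

    vectors, failures = [], []
    for record in report.final_records:
        try:
            exp = load(record.exp_source)
            model = load(record.model_source)
            vectors.append(feat.build_feature_vector(
                record, exp, model, sasa_points=config.sasa_points))
        except (ProsfoldError, KeyError, OSError) as exc:
            failures.append({"pros_id": record.pros_id, "reason": str(exc)})
            log.warning("skipping %s: %s", record.pros_id, exc)
    if failures:
        (out / "failures.json").write_text(json.dumps(failures, indent=1))
    if not vectors:
        raise ProsfoldError("no segment produced a feature vector")

    table = feat.features_table(vectors)
    artifacts["features"] = out / "features.tsv"
    table.to_csv(artifacts["features"], sep="\t", index=False, na_rep="NA")

    rmsds = table["rmsd"].to_numpy(dtype=float)
    if config.boundaries is None:
        b1, b2 = statpipe.optimize_boundaries(rmsds, table, alpha=config.alpha)
        log.info("optimized boundaries: %.3f / %.3f", b1, b2)
    else:
        b1, b2 = config.boundaries
    labels = statpipe.classify_all(rmsds, b1, b2)
    classes = table[["pros_id", "rmsd"]].copy()
    classes["class"] = labels
    artifacts["classes"] = out / "classes.tsv"
    classes.to_csv(artifacts["classes"], sep="\t", index=False)
    counts = pd.Series(labels).value_counts()
    log.info("classes at (%.2f, %.2f): %s", b1, b2, counts.to_dict())

    selection = statpipe.select_features(table, labels, alpha=config.alpha)
    artifacts["selection"] = out / "selection.tsv"
    selection.to_frame().to_csv(artifacts["selection"], sep="\t", index=False)
    selected = [f for f in selection.selected
                if not config.feature_subset or f in config.feature_subset]
    log.info("selected %d features: %s", len(selected), selected)
    if len(selected) < 3:
        raise ProsfoldError(
            f"only {len(selected)} features selected; need >= 3 for grouping")

    kept, dropped = statpipe.drop_collinear(table[selected])
    if dropped:
        log.warning("dropping collinear features before regression: %s", dropped)
    if len(kept) < 3:
        raise ProsfoldError(
            f"only {len(kept)} independent selected features; need >= 3")
    sub = table[["pros_id"] + kept]
    model = statpipe.fit_regression(sub, rmsds, outlier_threshold=config.outlier_threshold)
    artifacts["model"] = out / "model.json"
    artifacts["model"].write_text(json.dumps(
        {**model.to_dict(), "boundaries": [b1, b2]}, indent=1))
    log.info("regression: R^2=%.3f r=%.3f on %d segments", model.r_squared,
             model.pearson_r, model.n_used)

    groups = statpipe.cluster_features(sub, rmsds)
    artifacts["groups"] = out / "groups.json"
    artifacts["groups"].write_text(json.dumps(groups.to_dict(), indent=1))

    assignment = statpipe.assign_groups(model, groups, sub)
    assignment["class"] = labels
    artifacts["assignment"] = out / "assignment.tsv"
    assignment.to_csv(artifacts["assignment"], sep="\t", index=False)
    return artifacts
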