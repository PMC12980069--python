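"""End-to-end orchestration: validate -> features -> E-scores -> associations.

Artifacts written to the output directory:

* ``features.csv``      participants x indices (empty cell = missing)
* ``grouping.json``     index -> group, loadings, inertia curve, stability
* ``escores.csv``       participant_id, escore1..k
* ``associations.csv``  one row per test with adjusted p
* ``report.json``       run metadata: seed, config hash, row counts, versions
* ``run.log``           stage-by-stage log
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .escore import derive_escores
from .indices import build_feature_matrix, catalog_from_json, default_catalog
from .schemas import read_participants, read_trials, validate_cohort
from .stats import association_battery

logger = logging.getLogger("emocog")


class PipelineConfig(BaseModel):
    """Configuration for a full pipeline run."""

    trials: Path
    participants: Path
    out_dir: Path
    catalog: Path | None = None
    seed: int = 0
    #: number of feature groups; None = choose by the inertia elbow
    k: int | None = 3
    k_max: int = Field(8, ge=4)
    restarts: int = Field(50, ge=1)
    ancova_ss: int = 2
    dropout_threshold: int = Field(4, ge=1)
    compute_stability: bool = True
    mutual_control: bool = False
    alpha: float = Field(0.05, gt=0, lt=1)
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the artifact paths."""
    # fail on unreadable inputs before any output is produced
    for path in (config.trials, config.participants):
        if not Path(path).exists():
            raise FileNotFoundError(path)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict[str, Path]:
    logger.info("emocog %s | seed=%d | config=%s",
                __version__, config.seed, config.config_hash())

    trials = _stage("read")(read_trials)(config.trials)
    participants = _stage("read")(read_participants)(config.participants)
    logger.info("loaded %d trials, %d participants", len(trials), len(participants))

    report = _stage("validate")(validate_cohort)(
        trials, participants, dropout_threshold=config.dropout_threshold)
    for v in report.violations:
        logger.warning("validation: %s", v)
    logger.info("dropout flags per task: %s", report.dropout_counts)

    catalog = (catalog_from_json(config.catalog) if config.catalog
               else default_catalog())
    features = _stage("features")(build_feature_matrix)(
        trials, participants, catalog, dropout_threshold=config.dropout_threshold)
    logger.info("feature matrix: %d x %d (%d excluded participants)",
                *features.values.shape, len(features.excluded))
    features.write(out / "features.csv")

    z, embedding, grouping, table, stability = _stage("escore")(derive_escores)(
        features, k=config.k, k_max=config.k_max, seed=config.seed,
        restarts=config.restarts, compute_stability=config.compute_stability)
    logger.info("k=%d groups; stability=%s; dropped constant columns: %s",
                grouping.k, stability, z.dropped_columns)
    table.scores.to_csv(out / "escores.csv")

    grouping_blob = {
        "k": grouping.k,
        "chosen_k": grouping.chosen_k_note,
        "labels": {name: int(g) for name, g in grouping.labels.items()},
        "loadings": {str(g): {n: float(v) for n, v in load.items()}
                     for g, load in table.loadings.items()},
        "anchors": {str(g): a for g, a in table.anchors.items()},
        "inertia": {str(k): float(v) for k, v in sorted(grouping.inertia.items())},
        "explained_variance_ratio_embedding":
            [float(v) for v in embedding.explained_variance_ratio],
        "loo_stability": stability,
        "dropped_columns": list(z.dropped_columns),
        "imputed_cells": int(z.imputed.to_numpy().sum()),
    }
    (out / "grouping.json").write_text(json.dumps(grouping_blob, indent=1))

    battery = _stage("associations")(association_battery)(
        table.scores, participants, ss_type=config.ancova_ss,
        alpha=config.alpha, mutual_control=config.mutual_control)
    rows = battery.partials.assign(test="partial_r")
    anc = battery.ancova.assign(test="ancova")
    associations = pd.concat([rows, anc], ignore_index=True)
    if battery.mutual_partials is not None:
        associations = pd.concat(
            [associations, battery.mutual_partials.assign(test="partial_r_mutual")],
            ignore_index=True)
    associations.to_csv(out / "associations.csv", index=False)

    run_report = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_trials": int(len(trials)),
        "n_participants": int(len(participants)),
        "n_analysed": int(len(features.values)),
        "excluded": features.excluded,
        "dropout_counts": report.dropout_counts,
        "n_indices": len(catalog),
        "n_validation_findings": len(report.violations),
        "k": grouping.k,
        "loo_stability": stability,
        "n_partial_tests": int(len(battery.partials)),
        "n_fdr_significant": int(battery.partials["significant"].sum()),
    }
    (out / "report.json").write_text(json.dumps(run_report, indent=1))
    logger.info("done: %d FDR-significant partial correlations",
                run_report["n_fdr_significant"])

    return {
        "features": out / "features.csv",
        "grouping": out / "grouping.json",
        "escores": out / "escores.csv",
        "associations": out / "associations.csv",
        "report": out / "report.json",
        "log": out / "run.log",
    }


def summarize(bundle_dir: str | Path) -> str:
    """Human-readable summary of a completed artifact bundle."""
    out = Path(bundle_dir)
    needed = ["report.json", "grouping.json", "escores.csv", "associations.csv"]
    missing = [f for f in needed if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete bundle, missing: {missing}")
    report = json.loads((out / "report.json").read_text())
    grouping = json.loads((out / "grouping.json").read_text())
    escores = pd.read_csv(out / "escores.csv")
    associations = pd.read_csv(out / "associations.csv")

    lines = [
        f"emocog run (seed {report['seed']}, config {report['config_hash']})",
        f"participants: {report['n_participants']} total, "
        f"{report['n_analysed']} analysed, {len(report['excluded'])} excluded",
        f"exclusions per task: {report['dropout_counts'] or 'none'}",
        f"feature groups: k={grouping['k']} "
        f"(LOO stability: {grouping['loo_stability']})",
    ]
    labels = pd.Series(grouping["labels"])
    for g in range(1, grouping["k"] + 1):
        members = labels[labels == g]
        lines.append(f"  group {g}: {len(members)} indices "
                     f"(anchor: {grouping['anchors'].get(str(g), '-')})")
    score_cols = [c for c in escores.columns if c.startswith("escore")]
    lines.append(f"E-scores computed: {len(score_cols)} "
                 f"({', '.join(score_cols)}) for {len(escores)} participants")

    partials = associations[associations["test"] == "partial_r"]
    if len(partials) == 0:
        lines.append("associations: no tests run")
    else:
        lines.append(f"age-controlled partial correlations ({len(partials)} tests, "
                     "BH-FDR adjusted):")
        for row in partials.itertuples(index=False):
            flag = "*" if row.significant else " "
            lines.append(f"  {flag} {row.escore} ~ {row.scale}: r={row.r:+.3f} "
                         f"(p_fdr={row.p_fdr:.4f}, n={row.n})")
    return "\n".join(lines)
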