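"""End-to-end orchestration: simulate/ingest -> preprocess -> features ->
condition -> univariate select -> cluster -> RFE + logistic fit ->
threshold + evaluate, with a run manifest and a report laid out like the
train/test performance tables (AUC, then Sen/Spe/adjusted PPV per
threshold and night).

A single top-level seed (``config.seed``) is expanded deterministically
into per-stage seeds.  When an output directory is given, each stage's
table is written as TSV keyed by the config hash; the expensive feature
stage is resumable from its cached output.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sfio
from .classifier import (
    DEFAULT_FOLDS,
    DEFAULT_PREVALENCE,
    TARGET_SENSITIVITIES,
    EvalMetrics,
    FittedClassifier,
    attach_thresholds,
    evaluate,
    fit_logistic,
    rfe_cv,
)
from .clustering import cluster_features, dcor_matrix, pick_representatives
from .conditioning import condition_features
from .features import assemble_features, expected_feature_count, feature_columns
from .preprocessing import preprocess_recording, rejection_summary
from .selection import select_features
from .synthetic import CohortConfig, metadata_frame, simulate_cohort, simulate_feature_table


@dataclass
class PipelineResult:
    feature_table: pd.DataFrame
    conditioned: pd.DataFrame
    conditioning_report: object
    selection_records: pd.DataFrame
    selected: list[str]
    clusters: object
    reduced: list[str]
    final_features: list[str]
    model: FittedClassifier
    metrics: list[EvalMetrics]
    manifest: dict = field(default_factory=dict)

    @property
    def report_text(self) -> str:
        return format_report(self.metrics, self.final_features)


def _stage_seed(seed: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode())  # stable across processes
    ss = np.random.SeedSequence([seed, tag])
    return int(ss.generate_state(1)[0] % (2**31))


def apply_orientation(table: pd.DataFrame, records: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Multiply each feature by its fixed orientation sign so larger
    values always point toward the PTSD class."""
    table = table.copy()
    for f in features:
        table[f] = table[f] * records.loc[f, "orientation"]
    return table


def select_cluster_rfe(
    table: pd.DataFrame,
    n_folds: int = DEFAULT_FOLDS,
    rfe_seed: int = 0,
    rfe_criterion: str = "bic",
):
    """Univariate AUC selection, distance-correlation clustering and RFE
    (the feature-funnel stages on an already-conditioned table).

    Returns (selection records, selected features, cluster result,
    reduced set, final features, oriented table).
    """
    records = select_features(table)
    selected = list(records.index[records["selected"]])
    if not selected:
        raise RuntimeError("univariate selection retained no features; cannot continue")
    oriented = apply_orientation(table, records, selected)
    train = oriented[oriented["split"] == "train"]
    concat = train.sort_values(["night", "subject_id"]).reset_index(drop=True)
    dmat = dcor_matrix(concat[selected])
    clusters = pick_representatives(cluster_features(dmat), records)
    reduced = clusters.reduced_set
    final = rfe_cv(concat, reduced, n_folds=n_folds, seed=rfe_seed, criterion=rfe_criterion)
    return records, selected, clusters, reduced, final, oriented


def compute_feature_stage(config: CohortConfig, tier: str, out_dir: Path | None, resume: bool) -> tuple[pd.DataFrame, dict]:
    info: dict = {"tier": tier}
    cache = None
    if out_dir is not None:
        cache = out_dir / f"features.{config.config_hash()}.tsv"
        if resume and cache.exists():
            info["cached"] = True
            return sfio.read_table(cache), info
    if tier == "table":
        table = simulate_feature_table(config)
    elif tier == "signal":
        recordings, metas = simulate_cohort(config)
        grids = [preprocess_recording(r) for r in recordings]
        info["rejection"] = {
            f"{g.subject_id}-n{g.night}": rejection_summary(g) for g in grids
        }
        table = assemble_features(
            grids, metadata_frame(metas), required_channels=list(config.channels)
        )
    else:
        raise ValueError(f"unknown tier {tier!r}; use 'table' or 'signal'")
    if cache is not None:
        sfio.write_table(table, cache, sidecar={"config_hash": config.config_hash(), "seed": config.seed})
    return table, info


def run_pipeline(
    config: CohortConfig,
    tier: str = "table",
    out_dir: str | Path | None = None,
    prevalence: float = DEFAULT_PREVALENCE,
    targets: tuple[float, ...] = TARGET_SENSITIVITIES,
    n_folds: int = DEFAULT_FOLDS,
    rfe_criterion: str = "bic",
    include_test: bool = True,
    resume: bool = True,
) -> PipelineResult:
    """Run the full workflow on a synthetic cohort.

    ``tier='table'`` uses the fast feature-level generator; ``'signal'``
    synthesises raw EEG and runs preprocessing + spectral features.
    ``include_test=False`` drops test rows right after feature
    computation — training artifacts must be identical either way (the
    leak check).
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    table, feat_info = compute_feature_stage(config, tier, out_path, resume)
    n_features = len(feature_columns(table))
    expected = expected_feature_count(len(config.channels), 12)
    feat_info.update({"rows": len(table), "features": n_features, "expected_features": expected})
    manifest["stages"]["features"] = feat_info

    if not include_test:
        table = table[table["split"] == "train"].reset_index(drop=True)

    conditioned, cond_report = condition_features(table)
    manifest["stages"]["condition"] = {
        "retained": len(cond_report.retained),
        "age_corrected": len(cond_report.age_corrected),
    }

    records, selected, clusters, reduced, final, oriented = select_cluster_rfe(
        conditioned,
        n_folds=n_folds,
        rfe_seed=_stage_seed(config.seed, "rfe"),
        rfe_criterion=rfe_criterion,
    )
    manifest["stages"]["select"] = {"in": len(records), "selected": len(selected)}
    manifest["stages"]["cluster"] = {
        "clusters": len(clusters.clusters),
        "independents": len(clusters.independents),
        "reduced": len(reduced),
    }
    train = oriented[oriented["split"] == "train"]
    concat = train.sort_values(["night", "subject_id"]).reset_index(drop=True)
    model = fit_logistic(concat, final)
    model = attach_thresholds(model, concat, targets)
    manifest["stages"]["train"] = {"final_features": final, "thresholds": dict(model.thresholds)}

    metrics: list[EvalMetrics] = []
    for target in targets:
        cutoff = model.thresholds[target]
        metrics.append(evaluate(model, concat, cutoff, prevalence))
        if include_test:
            test = oriented[oriented["split"] == "test"]
            for night in sorted(test["night"].unique()):
                metrics.append(evaluate(model, test[test["night"] == night], cutoff, prevalence))
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    result = PipelineResult(
        feature_table=table,
        conditioned=conditioned,
        conditioning_report=cond_report,
        selection_records=records,
        selected=selected,
        clusters=clusters,
        reduced=reduced,
        final_features=final,
        model=model,
        metrics=metrics,
        manifest=manifest,
    )
    if out_path is not None:
        _write_outputs(result, out_path, config)
    return result


def _write_outputs(result: PipelineResult, out: Path, config: CohortConfig) -> None:
    sidecar = {"config_hash": config.config_hash(), "seed": config.seed}
    sfio.write_table(result.conditioned, out / "conditioned.tsv", sidecar)
    sfio.write_table(
        result.conditioning_report.table.reset_index(), out / "conditioning_report.tsv"
    )
    sfio.write_table(result.selection_records.reset_index(), out / "selection_records.tsv")
    sfio.write_table(result.clusters.dcor.reset_index(), out / "dcor_matrix.tsv")
    (out / "model.json").write_text(result.model.to_json())
    rows = [vars(m) for m in result.metrics]
    sfio.write_table(pd.DataFrame(rows), out / "evaluation.tsv")
    (out / "report.txt").write_text(result.report_text)
    sfio.write_manifest(result.manifest, out / "manifest.json")


def feature_count_audit(manifest: dict, n_channels: int = 10, n_bands: int = 12) -> dict:
    """Check the feature enumeration identity C·B + C·B + C(C−1)/2·B
    against the manifest's feature stage; hard failure on mismatch."""
    expected = expected_feature_count(n_channels, n_bands)
    got = manifest["stages"]["features"]["features"]
    if got != expected:
        raise RuntimeError(
            f"feature count audit failed: {got} features, expected {expected} "
            f"for {n_channels} channels x {n_bands} bands"
        )
    return {"n_channels": n_channels, "n_bands": n_bands, "expected": expected, "observed": got}


def format_report(metrics: list[EvalMetrics], final_features: list[str]) -> str:
    """Human-readable summary mirroring the performance-table layout."""
    lines = [
        "Final model features: " + ", ".join(final_features),
        "",
        f"{'':12s}{'Training':>12s}{'Test N1':>12s}{'Test N2':>12s}",
    ]

    def slot(m: EvalMetrics) -> str:
        if m.split == "train":
            return "Training"
        return f"Test N{m.night}"

    by_thr: dict[float, dict[str, EvalMetrics]] = {}
    for m in metrics:
        by_thr.setdefault(round(m.threshold, 6), {})[slot(m)] = m

    first = True
    for thr, slots in by_thr.items():
        if first:
            aucs = [
                f"{slots[s].auc:.2f}" if s in slots and np.isfinite(slots[s].auc) else "-"
                for s in ("Training", "Test N1", "Test N2")
            ]
            lines.append(f"{'AUC':12s}" + "".join(f"{a:>12s}" for a in aucs))
            first = False
        lines.append(f"Threshold = {thr:.2f}")
        for label, attr in (("Sen.", "sensitivity"), ("Spe.", "specificity"), ("Adj. PPV", "adjusted_ppv")):
            vals = []
            for s in ("Training", "Test N1", "Test N2"):
                if s in slots and np.isfinite(getattr(slots[s], attr)):
                    vals.append(f"{getattr(slots[s], attr):.2f}")
                else:
                    vals.append("-")
            lines.append(f"{label:12s}" + "".join(f"{v:>12s}" for v in vals))
    return "\n".join(lines) + "\n"
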