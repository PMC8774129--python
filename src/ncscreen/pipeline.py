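"""End-to-end orchestration: config, staged runs, external validation.

A run executes: load cohort -> resampled splits -> (optional) stability
selection per resample -> accumulation curve per resample -> turning
point -> final model at the stable panel size -> evaluation report.
Every stage derives its own seed from the master seed by hashing the
stage name, writes its outputs as plain-text files, and appends a log
line carrying seeds, parameters and input checksums; rerunning the same
config reproduces all deterministic artifacts byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .evaluation import (
    AccumulationCurve,
    accumulation_curve,
    auc,
    roc_curve,
    turning_point,
)
from .expression_io import (
    NORMAL_LABEL,
    ExpressionMatrix,
    MarkerPanel,
    intersect_markers,
    read_expression_matrix,
    read_labels,
    read_marker_panel,
    split_samples,
    write_marker_panel,
)
from .nn_models import NNConfig, build_model, predict_scores, train_model
from .stability_select import (
    StabilityParams,
    derive_resample_seed,
    select_stable_features,
)

__all__ = [
    "PipelineConfig",
    "PipelineConfigError",
    "run_pipeline",
    "validate_external",
    "derive_stage_seed",
]


class PipelineConfigError(ValueError):
    """Raised before any compute when a configuration does not validate."""


def derive_stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: sha256 of ``"<master>:<stage>"``, < 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full pipeline run.

    ``panel`` may be a path to a marker-panel TSV or ``"select"`` to run
    stability selection on each training resample. Defaults mirror the
    pipeline's standard operating point: 20%/20% splits, m=2 subgroups,
    fixed-architecture networks, alpha 0.1 and window 10 for the
    turning-point scan.
    """

    expression: str
    labels: str
    out_dir: str
    panel: str = "select"
    task: str = "binary"
    master_seed: int = 0
    test_frac: float = 0.2
    val_frac: float = 0.2
    n_resamples: int = 8
    K: int = 56
    alpha: float = 0.1
    window: int = 10
    stability: StabilityParams = field(default_factory=StabilityParams)
    nn: NNConfig = field(default_factory=NNConfig)
    k_grid_step: int = 1

    def __post_init__(self) -> None:
        if self.task not in ("binary", "multiclass"):
            raise PipelineConfigError("task must be 'binary' or 'multiclass'")
        for name in ("expression", "labels"):
            p = Path(getattr(self, name))
            if not p.is_file():
                raise PipelineConfigError(f"{name} file not found: {p}")
        if self.panel != "select" and not Path(self.panel).is_file():
            raise PipelineConfigError(f"panel file not found: {self.panel}")
        if self.n_resamples < 2:
            raise PipelineConfigError(
                "n_resamples must be >= 2 (the turning point compares runs)"
            )
        if self.k_grid_step < 1:
            raise PipelineConfigError("k_grid_step must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise PipelineConfigError(f"{path}: config must be a mapping")
        stability = StabilityParams(**raw.pop("stability", {}))
        nn_raw = raw.pop("nn", {})
        if "layer_widths" in nn_raw and nn_raw["layer_widths"] is not None:
            nn_raw["layer_widths"] = tuple(nn_raw["layer_widths"])
        nn = NNConfig(task=raw.get("task", "binary"), **nn_raw)
        try:
            return cls(stability=stability, nn=nn, **raw)
        except TypeError as exc:
            raise PipelineConfigError(f"{path}: {exc}") from None


def _load_cohort(config: PipelineConfig) -> tuple[ExpressionMatrix, np.ndarray]:
    matrix = read_expression_matrix(config.expression)
    labels = read_labels(config.labels)
    if list(labels.index) != matrix.sample_ids:
        labels = labels.reindex(matrix.sample_ids)
        if labels.isna().any():
            raise PipelineConfigError("labels do not cover every sample id")
    labels = labels.to_numpy()
    if config.task == "multiclass" and NORMAL_LABEL in labels:
        keep = labels != NORMAL_LABEL
        matrix = ExpressionMatrix(matrix.data.loc[keep].copy())
        labels = labels[keep]
    return matrix, labels


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full screen; returns the artifact directory.

    Artifacts: per-resample marker panels and accumulation-curve CSVs,
    the Kruskal–Wallis p-trace, a JSON summary (turning point, final
    test metric), ROC points for binary tasks, and ``run.log``.
    """
    out = Path(config.out_dir)
    (out / "panels").mkdir(parents=True, exist_ok=True)
    (out / "curves").mkdir(exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, **info) -> None:
        payload = json.dumps(info, sort_keys=True, default=str)
        log_lines.append(f"[{stage}] {payload}")

    log(
        "inputs",
        expression=config.expression,
        labels=config.labels,
        expression_sha256=_sha256(Path(config.expression)),
        labels_sha256=_sha256(Path(config.labels)),
        master_seed=config.master_seed,
    )
    matrix, labels = _load_cohort(config)
    log("load", n_samples=matrix.n_samples, n_features=matrix.n_features,
        task=config.task)

    fixed_panel = None
    if config.panel != "select":
        fixed_panel = read_marker_panel(config.panel)
        log("panel", source=config.panel, size=len(fixed_panel))

    split_seed = derive_stage_seed(config.master_seed, "split")
    select_seed = derive_stage_seed(config.master_seed, "select")
    model_seed = derive_stage_seed(config.master_seed, "model")

    curves: list[AccumulationCurve] = []
    splits = []
    panels: list[MarkerPanel] = []
    for i in range(config.n_resamples):
        seed_i = derive_resample_seed(split_seed, i)
        split = split_samples(
            matrix.n_samples, config.test_frac, config.val_frac, seed=seed_i
        )
        splits.append(split)
        if fixed_panel is None:
            train_X = matrix.take_samples(split.train_idx)
            params = replace(
                config.stability, seed=derive_resample_seed(select_seed, i)
            )
            panel, _ = select_stable_features(
                train_X, labels[split.train_idx], params
            )
            log("select", resample=i, panel_size=len(panel),
                stable=len(panel.stable_ids), seed=params.seed)
        else:
            panel = fixed_panel
        panels.append(panel)
        write_marker_panel(panel, out / "panels" / f"panel_{i}.tsv")
        K = min(config.K, len(panel))
        grid = list(range(1, K + 1, config.k_grid_step))
        if grid[-1] != K:
            grid.append(K)
        curve = accumulation_curve(
            panel, matrix, labels, split,
            model_kind="nn", seed=derive_resample_seed(model_seed, i),
            task=config.task, nn_config=config.nn, ks=grid,
        )
        curve.as_dataframe().to_csv(out / "curves" / f"curve_{i}.csv", index=False)
        curves.append(curve)
        log("accumulate", resample=i, split_seed=seed_i, K=K,
            final_metric=float(curve.metric[-1]))

    tp = turning_point(curves, alpha=config.alpha, window=config.window)
    tp.p_trace.rename_axis("k").to_csv(out / "p_trace.csv")
    log("turning_point", k_star=tp.k_star, found=tp.found,
        mean_metric=tp.mean_accuracy_at_k_star)

    # final model at the stable panel size (fall back to K if no stable point)
    k_final = tp.k_star if tp.found else int(curves[0].ks[-1])
    final_panel, final_split = panels[0], splits[0]
    feats = final_panel.top(min(k_final, len(final_panel)))
    nn_cfg = replace(config.nn, task=config.task, seed=model_seed)
    n_classes = 2 if config.task == "binary" else len(set(labels))
    net = build_model(len(feats), n_classes, nn_cfg)
    sub = matrix.restrict_features(feats)
    trained, history = train_model(
        net,
        sub.take_samples(final_split.train_idx), labels[final_split.train_idx],
        sub.take_samples(final_split.val_idx), labels[final_split.val_idx],
        nn_cfg,
    )
    history.as_dataframe().to_csv(out / "final_history.csv", index=False)
    test_scores = predict_scores(trained, sub.take_samples(final_split.test_idx))
    yte = labels[final_split.test_idx]
    if config.task == "binary":
        final_metric = auc(test_scores, yte != NORMAL_LABEL)
        roc = roc_curve(test_scores, yte != NORMAL_LABEL)
        roc.as_dataframe().to_csv(out / "final_roc.csv", index=False)
    else:
        lookup = {c: i for i, c in enumerate(trained.classes)}
        final_metric = float(
            np.mean(np.argmax(test_scores, axis=1)
                    == np.array([lookup[c] for c in yte]))
        )
    log("final_model", k=len(feats), metric=final_metric)

    summary = {
        "task": config.task,
        "n_resamples": config.n_resamples,
        "alpha": config.alpha,
        "window": config.window,
        "k_star": tp.k_star,
        "turning_point_found": tp.found,
        "mean_metric_at_k_star": tp.mean_accuracy_at_k_star,
        "final_panel_size": len(feats),
        "final_test_metric": final_metric,
        "master_seed": config.master_seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def validate_external(
    matrix: ExpressionMatrix,
    labels,
    panel: MarkerPanel,
    external_matrix: ExpressionMatrix,
    external_labels,
    task: str = "binary",
    seed: int = 0,
    test_frac: float = 0.2,
    val_frac: float = 0.2,
    nn_config: NNConfig | None = None,
    low_overlap_threshold: int = 10,
) -> dict:
    """Validate a marker panel on an independent cohort.

    The panel is intersected with the external cohort's feature
    identifiers; a model is retrained on the discovery cohort restricted
    to the matched markers, and the whole external cohort — raw values,
    no filtering or normalization — is scored as a test set. Reports the
    matched-marker count and the external AUC (binary) or accuracy, and
    flags low overlap (few matched markers make the screen unstable).
    """
    labels = np.asarray(labels)
    external_labels = np.asarray(external_labels)
    _, matched_panel, report = intersect_markers(external_matrix, panel)
    feats = matched_panel.feature_ids
    disc = matrix.restrict_features(feats)
    split = split_samples(disc.n_samples, test_frac, val_frac, seed=seed)
    cfg = nn_config or NNConfig(task=task)
    cfg = replace(cfg, task=task, seed=seed)
    n_classes = 2 if task == "binary" else len(set(labels))
    net = build_model(len(feats), n_classes, cfg)
    trained, _ = train_model(
        net,
        disc.take_samples(split.train_idx), labels[split.train_idx],
        disc.take_samples(split.val_idx), labels[split.val_idx],
        cfg,
    )
    ext = external_matrix.restrict_features(feats)
    scores = predict_scores(trained, ext)
    internal_scores = predict_scores(trained, disc.take_samples(split.test_idx))
    if task == "binary":
        external_metric = auc(scores, external_labels != NORMAL_LABEL)
        internal_metric = auc(
            internal_scores, labels[split.test_idx] != NORMAL_LABEL
        )
    else:
        lookup = {c: i for i, c in enumerate(trained.classes)}
        external_metric = float(np.mean(
            np.argmax(scores, axis=1)
            == np.array([lookup[c] for c in external_labels])
        ))
        internal_metric = float(np.mean(
            np.argmax(internal_scores, axis=1)
            == np.array([lookup[c] for c in labels[split.test_idx]])
        ))
    return {
        "n_matched": report.n_matched,
        "n_missing": report.n_missing,
        "missing": list(report.missing),
        "low_overlap": report.n_matched < low_overlap_threshold,
        "external_metric": external_metric,
        "internal_test_metric": internal_metric,
        "task": task,
        "metric_name": "auc" if task == "binary" else "accuracy",
    }
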