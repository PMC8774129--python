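"""ROC/AUC, accumulation curves, Kruskal–Wallis, and the turning point.

The central question these tools answer: as biomarkers are added one at
a time in frequency-rank order, how does classifier performance grow,
and at what panel size does performance stop depending on which random
training resample produced the panel? The latter is located by running
a Kruskal–Wallis rank-sum test across independent runs' accuracy traces
at every panel size and finding the last size before the runs diverge
(p falling below ``alpha``, default 0.1). That size is the *turning
point*: the largest panel whose accuracy is independent of training-set
sampling, and hence the stable operating point of the screen.

AUC is defined here as the Mann–Whitney concordance — the probability
that a random positive outscores a random negative, ties counted half —
computed from rank statistics; the trapezoidal area under the ROC curve
is the cross-check (they agree to numerical precision).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .expression_io import NORMAL_LABEL, DataSplit, ExpressionMatrix, MarkerPanel
from .nn_models import NNConfig, build_baseline, build_model, train_model

__all__ = [
    "ROCCurve",
    "AccumulationCurve",
    "TurningPointResult",
    "ModelComparison",
    "auc",
    "roc_curve",
    "kruskal_wallis",
    "accumulation_curve",
    "turning_point",
    "compare_models",
]

MODEL_KINDS = ("nn", "random_forest", "decision_tree")


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def _check_binary(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels, dtype=float).astype(bool)
    if y.all() or not y.any():
        raise ValueError("AUC requires both a positive and a negative class")
    return y


def auc(scores: Sequence[float], labels: Sequence) -> float:
    """Mann–Whitney concordance: P(score+ > score-) + 0.5 P(score+ = score-).

    Computed via mid-ranks, so ties are handled exactly; invariant under
    any strictly monotone transform of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(scores)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-sweep ROC: (FPR, TPR) pairs from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        f, t = np.asarray(self.fpr), np.asarray(self.tpr)
        if not (f[0] == 0 and t[0] == 0 and f[-1] == 1 and t[-1] == 1):
            raise ValueError("ROC must begin at (0,0) and end at (1,1)")
        if (np.diff(f) < 0).any() or (np.diff(t) < 0).any():
            raise ValueError("ROC coordinates must be non-decreasing")

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        )


def roc_curve(scores: Sequence[float], labels: Sequence) -> ROCCurve:
    """Full ROC with one point per distinct threshold plus endpoints;
    its trapezoidal area equals :func:`auc` to numerical precision."""
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), scores, drop_intermediate=False)
    if fpr[-1] != 1 or tpr[-1] != 1:  # defensive; sklearn always ends at (1,1)
        fpr = np.append(fpr, 1.0)
        tpr = np.append(tpr, 1.0)
        thr = np.append(thr, -np.inf)
    area = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr, tpr, thr, area)


# ---------------------------------------------------------------------------
# Kruskal–Wallis
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H on mid-ranks with tie correction.

    H = 12 / (N (N+1)) * sum_i R_i^2 / n_i - 3 (N+1), divided by the tie
    correction 1 - sum(t^3 - t) / (N^3 - N); the p-value comes from the
    chi-square approximation with (k - 1) degrees of freedom. Groups of
    entirely identical observations give (H, p) = (0, 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)].sum()
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n_total**3 - n_total)
    h /= correction
    p = float(chi2.sf(h, len(groups) - 1))
    return float(h), p


# ---------------------------------------------------------------------------
# accumulation curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AccumulationCurve:
    """Metric vs accumulated-marker count for one run (one split/panel)."""

    ks: np.ndarray
    metric: np.ndarray
    train_loss: np.ndarray
    val_loss: np.ndarray
    metric_name: str  # "auc" or "accuracy"
    model_kind: str
    run_seed: int

    def __post_init__(self) -> None:
        ks = np.asarray(self.ks, dtype=int)
        if (np.diff(ks) <= 0).any():
            raise ValueError("marker counts must be strictly increasing")
        for arr in (self.metric, self.train_loss, self.val_loss):
            if not np.isfinite(np.asarray(arr, dtype=float)).all():
                raise ValueError("curve metrics must be finite")

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.ks,
                self.metric_name: self.metric,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
            }
        )


def _log_loss(probs: np.ndarray, y: np.ndarray, task: str) -> float:
    eps = 1e-12
    if task == "binary":
        p = np.clip(probs, eps, 1 - eps)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    p = np.clip(probs[np.arange(len(y)), y], eps, None)
    return float(-np.mean(np.log(p)))


def _fit_eval_one(
    feats: list[str],
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    split: DataSplit,
    model_kind: str,
    task: str,
    seed: int,
    nn_config: NNConfig | None,
) -> tuple[float, float, float]:
    """Train one fresh model on the top-k features; return
    (test metric, final train loss, final val loss)."""
    sub = matrix.restrict_features(feats)
    Xtr, Xva, Xte = (sub.take_samples(i) for i in
                     (split.train_idx, split.val_idx, split.test_idx))
    ytr_s, yva_s, yte_s = (labels[i] for i in
                           (split.train_idx, split.val_idx, split.test_idx))
    if model_kind == "nn":
        cfg = nn_config or NNConfig(task=task)
        cfg = replace(cfg, task=task, seed=seed)
        net = build_model(len(feats), 2 if task == "binary" else
                          len(set(labels)), cfg)
        trained, history = train_model(net, Xtr, ytr_s, Xva, yva_s, cfg)
        scores = trained.net.predict_proba(
            np.log1p(Xte.values) if cfg.log_transform else Xte.values
        )
        train_loss, val_loss = history.train_loss[-1], history.val_loss[-1]
        if task == "binary":
            metric = auc(scores, (yte_s != NORMAL_LABEL))
        else:
            pred = np.argmax(scores, axis=1)
            lookup = {c: i for i, c in enumerate(trained.classes)}
            metric = float(np.mean(pred == np.array([lookup[c] for c in yte_s])))
        return metric, train_loss, val_loss

    est = build_baseline(model_kind, seed=seed)
    # encode against the union of classes so a class absent from the
    # training subset cannot shift the probability column order
    all_classes = tuple(sorted(set(labels))) if task == "multiclass" else None
    if task == "binary":
        ytr = (ytr_s != NORMAL_LABEL).astype(float)
        yva = (yva_s != NORMAL_LABEL).astype(float)
        yte = (yte_s != NORMAL_LABEL).astype(float)
    else:
        lookup = {c: i for i, c in enumerate(all_classes)}
        ytr = np.array([lookup[c] for c in ytr_s])
        yva = np.array([lookup[c] for c in yva_s])
        yte = np.array([lookup[c] for c in yte_s])
    est.fit(Xtr.values, ytr)

    def _proba(A: np.ndarray) -> np.ndarray:
        raw = est.predict_proba(A)
        if task == "binary":
            return raw[:, list(est.classes_).index(1.0)]
        full = np.zeros((len(A), len(all_classes)))
        for col, cls in enumerate(est.classes_):
            full[:, int(cls)] = raw[:, col]
        return full

    proba_tr, proba_va, proba_te = (_proba(X.values) for X in (Xtr, Xva, Xte))
    train_loss = _log_loss(proba_tr, ytr.astype(int), task)
    val_loss = _log_loss(proba_va, yva.astype(int), task)
    if task == "binary":
        metric = auc(proba_te, yte)
    else:
        metric = float(np.mean(np.argmax(proba_te, axis=1) == yte))
    return metric, train_loss, val_loss


def accumulation_curve(
    panel: MarkerPanel,
    matrix: ExpressionMatrix,
    labels: Sequence[str],
    split: DataSplit,
    model_kind: str = "nn",
    K: int | None = None,
    seed: int = 0,
    task: str = "binary",
    nn_config: NNConfig | None = None,
    ks: Sequence[int] | None = None,
) -> AccumulationCurve:
    """Performance as markers accumulate 1..K in panel-rank order.

    For every k a *fresh* model is trained on the training split using
    only the top-k panel features; the recorded metric is test-set AUC
    (binary) or test-set accuracy (multiclass), along with the final
    training and validation losses. ``ks`` may thin the grid (e.g. every
    5th count) for large panels.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    labels = np.asarray(labels)
    if K is None:
        K = len(panel)
    if K > len(panel):
        raise ValueError(f"K={K} exceeds panel size {len(panel)}")
    grid = list(ks) if ks is not None else list(range(1, K + 1))
    if any(k < 1 or k > len(panel) for k in grid):
        raise ValueError("every k must lie in 1..len(panel)")
    metrics, tr_losses, va_losses = [], [], []
    for k in grid:
        m, tl, vl = _fit_eval_one(
            panel.top(k), matrix, labels, split, model_kind, task, seed, nn_config
        )
        metrics.append(m)
        tr_losses.append(tl)
        va_losses.append(vl)
    return AccumulationCurve(
        np.array(grid),
        np.array(metrics),
        np.array(tr_losses),
        np.array(va_losses),
        metric_name="auc" if task == "binary" else "accuracy",
        model_kind=model_kind,
        run_seed=seed,
    )


# ---------------------------------------------------------------------------
# turning point
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TurningPointResult:
    """Stable panel size located by the run-divergence KW scan."""

    k_star: int | None
    found: bool
    mean_accuracy_at_k_star: float | None
    p_trace: pd.Series  # index: marker count k; values: KW p
    alpha: float
    window: int


def turning_point(
    curves: Sequence[AccumulationCurve],
    alpha: float = 0.1,
    window: int = 10,
) -> TurningPointResult:
    """Find the largest panel size before independent runs diverge.

    At each marker count ``k`` (from the ``window``-th grid point on),
    each run contributes its trailing window of metric values at counts
    ``k-window+1 .. k`` as one group, and the groups are compared with
    the Kruskal–Wallis test. ``k_star`` is the largest k such that
    p(j) >= alpha for every testable j <= k: the last point before
    sustained run-to-run divergence. If the very first testable point is
    already significant the result is flagged not found.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 runs")
    if window < 2:
        raise ValueError("window must be >= 2")
    grid = np.asarray(curves[0].ks)
    for c in curves[1:]:
        if not np.array_equal(np.asarray(c.ks), grid):
            raise ValueError("all curves must share the same marker-count grid")
    if len(grid) < window:
        raise ValueError(f"grid has {len(grid)} points; window={window} needs more")
    p_vals: dict[int, float] = {}
    k_star: int | None = None
    diverged = False
    for i in range(window - 1, len(grid)):
        groups = [c.metric[i - window + 1:i + 1] for c in curves]
        _, p = kruskal_wallis(groups)
        p_vals[int(grid[i])] = p
        if not diverged:
            if p >= alpha:
                k_star = int(grid[i])
            else:
                diverged = True
    found = k_star is not None
    mean_acc = None
    if found:
        pos = int(np.flatnonzero(grid == k_star)[0])
        mean_acc = float(np.mean([c.metric[pos] for c in curves]))
    return TurningPointResult(
        k_star=k_star,
        found=found,
        mean_accuracy_at_k_star=mean_acc,
        p_trace=pd.Series(p_vals, name="kw_p"),
        alpha=alpha,
        window=window,
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelComparison:
    """Accumulation curves for each model kind on identical splits, with
    a Kruskal–Wallis test across the models' metric traces."""

    curves: dict[str, AccumulationCurve]
    kw_h: float
    kw_p: float

    def best_model(self) -> str:
        return max(self.curves, key=lambda k: float(np.max(self.curves[k].metric)))


def compare_models(
    panel: MarkerPanel,
    matrix: ExpressionMatrix,
    labels: Sequence[str],
    split: DataSplit,
    K: int | None = None,
    seed: int = 0,
    task: str = "binary",
    model_kinds: Sequence[str] = MODEL_KINDS,
    nn_config: NNConfig | None = None,
    ks: Sequence[int] | None = None,
) -> ModelComparison:
    """Run every model kind on the same split/panel and test whether
    their accumulated-metric distributions differ (Kruskal–Wallis)."""
    curves = {
        kind: accumulation_curve(
            panel, matrix, labels, split, model_kind=kind, K=K, seed=seed,
            task=task, nn_config=nn_config, ks=ks,
        )
        for kind in model_kinds
    }
    h, p = kruskal_wallis([c.metric for c in curves.values()])
    return ModelComparison(curves=curves, kw_h=h, kw_p=p)
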