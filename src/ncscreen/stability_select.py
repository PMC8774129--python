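"""Resampling stability selection with frequency-score ranking.

The selection scheme: within a training cohort, samples are randomly
partitioned into ``m`` disjoint, equal-size (+/-1) subgroups; a
sparsity-inducing linear classifier is fitted to each subgroup and the
features with nonzero coefficients are the subgroup's preliminary
markers. The partition is redrawn ``n`` times, giving ``m * n`` runs in
total. A feature's *frequency score* is the fraction of completed runs
that selected it; features whose score reaches the consistency threshold
(default 1.0 — selected in every run) form the final biomarker set, and
the full ranking by frequency score is the marker panel consumed by the
accumulation-curve analysis downstream.

The base selector is an L1-penalized linear classifier fitted
one-vs-rest across classes (union of per-class supports). Features are
standardized inside each subgroup fit so that the L1 penalty compares
coefficients on a common scale — raw TPM spans orders of magnitude, and
an unscaled L1 fit would rank features by abundance rather than signal.
The standardization is internal to the selector; expression values
themselves are never altered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .expression_io import ExpressionMatrix, MarkerPanel, split_samples

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityParams",
    "SelectionCounts",
    "base_select",
    "select_stable_features",
    "rank_for_multiclass",
    "derive_resample_seed",
]

_BASE_SELECTORS = ("l1-linear-svm-ovr", "l1-logistic")
_COEF_TOL = 1e-8  # liblinear leaves tiny non-exact zeros occasionally


@dataclass(frozen=True)
class StabilityParams:
    """Stability-selection hyperparameters.

    ``m`` subgroups per iteration (>= 2), ``n`` iterations (the scheme is
    intended for n >= 100; smaller values are allowed for quick runs),
    ``consistency_threshold`` is the fraction of the m*n completed runs a
    feature must appear in to enter the final set (1.0 = strict
    intersection). ``regularization_strength`` is the L1 penalty weight
    (the inverse of scikit-learn's ``C``): larger means sparser.
    """

    m: int = 2
    n: int = 100
    consistency_threshold: float = 1.0
    base_selector: str = "l1-linear-svm-ovr"
    regularization_strength: float = 1.0
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m (subgroups) must be >= 2")
        if self.n < 1:
            raise ValueError("n (iterations) must be >= 1")
        if not (0 < self.consistency_threshold <= 1):
            raise ValueError("consistency_threshold must lie in (0, 1]")
        if self.base_selector not in _BASE_SELECTORS:
            raise ValueError(
                f"unknown base_selector {self.base_selector!r}; "
                f"choose one of {_BASE_SELECTORS}"
            )
        if self.regularization_strength <= 0:
            raise ValueError("regularization_strength must be positive")

    @property
    def total_planned_runs(self) -> int:
        return self.m * self.n


@dataclass(frozen=True)
class SelectionCounts:
    """Per-feature count of runs that selected the feature."""

    counts: pd.Series  # indexed by feature_id
    total_runs: int

    def __post_init__(self) -> None:
        if self.total_runs < 0:
            raise ValueError("total_runs must be >= 0")
        c = self.counts.to_numpy()
        if ((c < 0) | (c > self.total_runs)).any():
            raise ValueError("counts must lie in [0, total_runs]")

    @property
    def frequency_scores(self) -> pd.Series:
        if self.total_runs == 0:
            raise ValueError("no completed runs")
        return self.counts / self.total_runs

    def final_set(self, consistency_threshold: float) -> frozenset:
        """Features selected in at least ``threshold`` of completed runs."""
        freq = self.frequency_scores
        # small epsilon guards count/total just below threshold by float error
        keep = freq.index[freq.to_numpy() >= consistency_threshold - 1e-12]
        return frozenset(keep)


def _fit_support(X: np.ndarray, y01: np.ndarray, params: StabilityParams) -> np.ndarray:
    C = 1.0 / params.regularization_strength
    # random_state pins liblinear's internal shuffling: fits must be a
    # pure function of (data, params) for stability counts to reproduce
    if params.base_selector == "l1-linear-svm-ovr":
        est = LinearSVC(penalty="l1", dual=False, C=C, tol=1e-3, max_iter=5000,
                        random_state=0)
    else:
        est = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=C,
                                 max_iter=1000, random_state=0)
    est.fit(X, y01)
    return np.abs(np.ravel(est.coef_)) > _COEF_TOL


def base_select(
    X: np.ndarray | ExpressionMatrix,
    y: Sequence[str],
    params: StabilityParams,
) -> np.ndarray | None:
    """Select features within one subgroup; returns a boolean support mask.

    Fits one sparse binary classifier per class (one-vs-rest) and takes
    the union of nonzero-coefficient supports. Returns ``None`` when the
    subgroup is degenerate (a single class): such runs are skipped by the
    caller and excluded from the run denominator.
    """
    if isinstance(X, ExpressionMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        return None
    if params.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    if len(classes) == 2:
        return _fit_support(X, (y == classes[1]).astype(int), params)
    support = np.zeros(X.shape[1], dtype=bool)
    for cls in classes:
        support |= _fit_support(X, (y == cls).astype(int), params)
    return support


def select_stable_features(
    X: ExpressionMatrix,
    y: Sequence[str],
    params: StabilityParams,
) -> tuple[MarkerPanel, SelectionCounts]:
    """Run the full m-subgroup x n-iteration selection on one cohort.

    Returns the frequency-ranked panel of every feature selected at least
    once (ties broken by ascending feature id) together with the raw
    selection counts; the panel's ``stable_ids`` flags the final set at
    ``params.consistency_threshold``. Deterministic per ``params.seed``.
    """
    y = np.asarray(y)
    n_samples = X.n_samples
    if len(y) != n_samples:
        raise ValueError("labels are not aligned to the matrix")
    if n_samples < params.m * 2:
        raise ValueError(
            f"need at least m*2 = {params.m * 2} samples, got {n_samples}"
        )
    values = X.values
    rng = np.random.default_rng(params.seed)
    counts = np.zeros(X.n_features, dtype=int)
    completed = 0
    skipped = 0
    for _ in range(params.n):
        perm = rng.permutation(n_samples)
        for group in np.array_split(perm, params.m):
            support = base_select(values[group], y[group], params)
            if support is None:
                skipped += 1
                continue
            counts += support
            completed += 1
    if skipped:
        logger.info("skipped %d degenerate (single-class) runs", skipped)
    if completed == 0:
        raise RuntimeError(
            "every resampling run was degenerate (single class); "
            "cannot compute frequency scores"
        )
    series = pd.Series(counts, index=X.feature_ids, name="count")
    selection = SelectionCounts(series, completed)
    freq = selection.frequency_scores
    nonzero = freq[freq > 0]
    panel = MarkerPanel.from_scores(
        nonzero,
        provenance=(
            f"stability selection m={params.m} n={params.n} "
            f"selector={params.base_selector} "
            f"reg={params.regularization_strength} seed={params.seed} "
            f"completed_runs={completed}"
        ),
        stable_ids=selection.final_set(params.consistency_threshold),
    )
    return panel, selection


def derive_resample_seed(seed: int, index: int) -> int:
    """Per-resample seed stream: independent, reproducible, < 2**31."""
    child = np.random.SeedSequence(seed).spawn(index + 1)[index]
    return int(child.generate_state(1)[0] % (2**31))


def rank_for_multiclass(
    X: ExpressionMatrix,
    y: Sequence[str],
    params: StabilityParams,
    n_resamples: int = 8,
    test_frac: float = 0.2,
    val_frac: float = 0.2,
) -> list[MarkerPanel]:
    """Rank markers on ``n_resamples`` independent training resamples.

    Each resample re-splits the cohort (test/validation/train) with its
    own derived seed and runs :func:`select_stable_features` on the
    training set only — held-out samples never touch selection. Returns
    one frequency-ranked panel per resample; run-to-run agreement of
    these panels is what the turning-point analysis quantifies.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    y = np.asarray(y)
    panels: list[MarkerPanel] = []
    for i in range(n_resamples):
        seed_i = derive_resample_seed(params.seed, i)
        split = split_samples(X.n_samples, test_frac, val_frac, seed=seed_i)
        train_X = X.take_samples(split.train_idx)
        panel, _ = select_stable_features(
            train_X, y[split.train_idx], replace(params, seed=seed_i)
        )
        panels.append(panel)
    return panels
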