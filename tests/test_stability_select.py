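"""Stability selection: base selector sparsity, frequency aggregation,
multi-resample ranking, and agreement with rank-sum screening."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from ncscreen.expression_io import ExpressionMatrix
from ncscreen.stability_select import (
    StabilityParams,
    base_select,
    derive_resample_seed,
    rank_for_multiclass,
    select_stable_features,
)
from ncscreen.synthetic_data import SyntheticConfig, generate_cohort


def as_matrix(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"s{i}" for i in range(values.shape[0])],
            columns=[f"{prefix}{j:03d}" for j in range(values.shape[1])],
        )
    )


def separable_toy(seed=0, n=40, n_features=20, signal_col=3):
    """One feature perfectly separates the classes; the rest are noise."""
    rng = np.random.default_rng(seed)
    X = rng.lognormal(0, 0.5, size=(n, n_features))
    y = np.array(["normal"] * (n // 2) + ["cancer_01"] * (n // 2))
    X[y == "cancer_01", signal_col] += 50.0
    return X, y, signal_col


class TestBaseSelect:
    def test_perfectly_separating_feature_is_selected(self):
        X, y, signal_col = separable_toy()
        # independent oracle: exhaustive single-feature separability scan
        separable = [
            j for j in range(X.shape[1])
            if max(X[y == "normal", j]) < min(X[y == "cancer_01", j])
            or max(X[y == "cancer_01", j]) < min(X[y == "normal", j])
        ]
        assert separable == [signal_col]
        params = StabilityParams(regularization_strength=2.0)
        support = base_select(X, y, params)
        assert support[signal_col]

    def test_single_class_subgroup_is_skipped(self):
        X = np.random.default_rng(0).lognormal(size=(10, 5))
        assert base_select(X, ["normal"] * 10, StabilityParams()) is None

    def test_extreme_regularization_selects_nothing(self):
        X, y, _ = separable_toy()
        params = StabilityParams(regularization_strength=1e6)
        assert base_select(X, y, params).sum() == 0

    def test_l1_logistic_selector_agrees_on_the_signal(self):
        X, y, signal_col = separable_toy()
        params = StabilityParams(base_selector="l1-logistic",
                                 regularization_strength=2.0)
        assert base_select(X, y, params)[signal_col]

    def test_support_invariant_under_sample_permutation(self):
        X, y, _ = separable_toy(seed=5)
        params = StabilityParams(regularization_strength=2.0)
        before = base_select(X, y, params)
        perm = np.random.default_rng(1).permutation(len(y))
        after = base_select(X[perm], y[perm], params)
        np.testing.assert_array_equal(before, after)

    def test_multiclass_takes_union_of_per_class_supports(self):
        rng = np.random.default_rng(2)
        X = rng.lognormal(0, 0.5, size=(60, 10))
        y = np.repeat(["normal", "cancer_01", "cancer_02"], 20)
        X[y == "cancer_01", 1] += 50
        X[y == "cancer_02", 7] += 50
        support = base_select(X, y, StabilityParams(regularization_strength=2.0))
        assert support[1] and support[7]


class TestSelectStableFeatures:
    def test_forced_two_feature_outcome(self):
        # two hugely informative features among constant columns: every
        # run must select exactly {A, B}, so both score 1.0 and the
        # final set at threshold 1.0 is {A, B}
        rng = np.random.default_rng(0)
        X = np.zeros((40, 6))
        y = np.array(["normal"] * 20 + ["cancer_01"] * 20)
        X[:, 2] = rng.lognormal(0, 0.3, 40) + (y != "normal") * 40
        X[:, 4] = rng.lognormal(0, 0.3, 40) + (y != "normal") * 40
        matrix = as_matrix(X)
        params = StabilityParams(m=2, n=1, consistency_threshold=1.0, seed=0)
        panel, counts = select_stable_features(matrix, y, params)
        assert panel.entries == (("g002", 1.0), ("g004", 1.0))
        assert panel.stable_ids == {"g002", "g004"}
        assert counts.total_runs == 2

    def test_planted_markers_dominate_top_ranks(self, planted_cohort,
                                                planted_panel):
        matrix, labels, truth = planted_cohort
        panel, _ = planted_panel
        recovered = set(panel.top(10)) & truth.marker_ids
        assert len(recovered) >= 8
        # independent oracle: per-feature rank-sum screening agrees that
        # the planted features are the most class-associated ones
        pvals = {}
        for fid in matrix.feature_ids:
            col = matrix.data[fid]
            pvals[fid] = min(
                mannwhitneyu(col[labels == c], col[labels == "normal"]).pvalue
                for c in ("cancer_01", "cancer_02")
            )
        screened_top = set(sorted(pvals, key=pvals.get)[:10])
        assert len(screened_top & truth.marker_ids) >= 8

    def test_pure_noise_final_set_empty_at_strict_threshold(self):
        for seed in range(5):
            cfg = SyntheticConfig(
                n_classes=2, samples_per_class=(30, 30, 30), n_features=100,
                n_informative=0, effect_size=0.0, seed=seed,
            )
            matrix, labels, _ = generate_cohort(cfg)
            panel, _ = select_stable_features(
                matrix, np.asarray(labels),
                StabilityParams(m=2, n=100, consistency_threshold=1.0,
                                seed=seed),
            )
            assert panel.stable_ids == frozenset()

    def test_raising_threshold_never_enlarges_final_set(self, planted_panel):
        _, counts = planted_panel
        sets = [counts.final_set(t) for t in (0.2, 0.5, 0.8, 1.0)]
        for smaller_t, larger_t in zip(sets, sets[1:]):
            assert larger_t <= smaller_t

    def test_frequency_scores_bounded(self, planted_panel):
        panel, counts = planted_panel
        assert ((panel.scores >= 0) & (panel.scores <= 1)).all()
        assert counts.counts.sum() <= counts.total_runs * len(counts.counts)

    def test_all_degenerate_runs_is_an_error(self):
        X = as_matrix(np.random.default_rng(0).lognormal(size=(10, 4)))
        with pytest.raises(RuntimeError, match="degenerate"):
            select_stable_features(X, ["normal"] * 10,
                                   StabilityParams(m=2, n=2))

    def test_strong_single_feature_reaches_score_one(self):
        # frequency score of an overwhelming marker approaches 1.0
        for seed in range(3):
            X, y, signal_col = separable_toy(seed=seed, n=60)
            X[y == "cancer_01", signal_col] += 1000
            panel, _ = select_stable_features(
                as_matrix(X), y,
                StabilityParams(m=2, n=10, seed=seed,
                                regularization_strength=2.0),
            )
            assert dict(panel.entries)[f"g{signal_col:03d}"] == 1.0


class TestRankForMulticlass:
    def test_returns_one_sorted_panel_per_resample(self, planted_cohort):
        matrix, labels, _ = planted_cohort
        panels = rank_for_multiclass(
            matrix, labels, StabilityParams(m=2, n=3, seed=0), n_resamples=8
        )
        assert len(panels) == 8
        for p in panels:
            scores = p.scores
            assert (np.diff(scores) <= 0).all()

    def test_single_resample_matches_direct_call(self, planted_cohort):
        from ncscreen.expression_io import split_samples

        matrix, labels, _ = planted_cohort
        params = StabilityParams(m=2, n=3, seed=42)
        [panel] = rank_for_multiclass(matrix, labels, params, n_resamples=1)
        seed0 = derive_resample_seed(42, 0)
        split = split_samples(matrix.n_samples, 0.2, 0.2, seed=seed0)
        direct, _ = select_stable_features(
            matrix.take_samples(split.train_idx),
            labels[split.train_idx],
            replace(params, seed=seed0),
        )
        assert panel.entries == direct.entries

    def test_panels_agree_more_under_signal_than_noise(self, planted_cohort):
        def mean_jaccard(matrix, labels, seed):
            panels = rank_for_multiclass(
                matrix, labels, StabilityParams(m=2, n=5, seed=seed),
                n_resamples=4,
            )
            tops = [set(p.top(min(20, len(p)))) for p in panels]
            pairs = [
                len(a & b) / len(a | b)
                for i, a in enumerate(tops) for b in tops[i + 1:]
            ]
            return np.mean(pairs)

        matrix, labels, _ = planted_cohort
        cfg = SyntheticConfig(
            n_classes=2, samples_per_class=(50, 50, 50), n_features=200,
            n_informative=10, effect_size=0.0, seed=7,
        )
        noise_m, noise_l, _ = generate_cohort(cfg)
        assert mean_jaccard(matrix, labels, 0) > mean_jaccard(
            noise_m, np.asarray(noise_l), 0
        )
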