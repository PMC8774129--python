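"""Metrics: concordance AUC, ROC, Kruskal–Wallis, turning point,
accumulation curves and the three-model comparison."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import chi2
from scipy.stats import kruskal as scipy_kruskal

from ncscreen.evaluation import (
    AccumulationCurve,
    accumulation_curve,
    auc,
    compare_models,
    kruskal_wallis,
    roc_curve,
    turning_point,
)
from ncscreen.expression_io import MarkerPanel, split_samples
from ncscreen.synthetic_data import SyntheticConfig, generate_cohort


def brute_force_auc(scores, labels):
    """Pairwise concordance by explicit enumeration (the definition)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_concordant_pairs(self):
        assert auc([0.8, 0.3, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_all_tied_scores(self):
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive and a negative"):
            auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(4, 51)
            scores = np.round(rng.normal(size=n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.all() or not labels.any():
                continue
            assert abs(auc(scores, labels)
                       - brute_force_auc(scores, labels)) < 1e-12

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        assert auc(scores, labels) == auc(np.exp(scores), labels)

    def test_score_negation_symmetry(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=51)  # continuous, tie-free
        labels = np.array([0, 1] * 25 + [1])
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)


class TestROCCurve:
    def test_perfect_scores_pass_through_top_left(self):
        roc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        points = set(zip(roc.fpr, roc.tpr))
        assert (0.0, 1.0) in points
        assert roc.auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        roc = roc_curve(rng.normal(size=1000), rng.integers(0, 2, size=1000))
        assert 0.45 < roc.auc < 0.55

    def test_trapezoid_area_equals_concordance(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(5, 60)
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, size=n)
            if labels.all() or not labels.any():
                continue
            roc = roc_curve(scores, labels)
            assert abs(roc.auc - auc(scores, labels)) < 1e-12


class TestKruskalWallis:
    def test_hand_computed_three_group_example(self):
        # rank sums 6, 15, 24 -> H = (12/90)(12 + 75 + 192) - 30 = 7.2
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-12)
        assert p == pytest.approx(float(chi2.sf(7.2, 2)), abs=1e-12)

    def test_identical_groups_give_h_zero_p_one(self):
        assert kruskal_wallis([[1, 2, 3]] * 3) == (0.0, 1.0)
        assert kruskal_wallis([[5, 5], [5, 5, 5]]) == (0.0, 1.0)

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            k = int(rng.integers(2, 6))
            groups = [
                np.round(rng.normal(size=rng.integers(3, 15)), 1)
                for _ in range(k)
            ]
            h, p = kruskal_wallis(groups)
            ref = scipy_kruskal(*groups)
            assert h == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    @pytest.mark.parametrize(
        "groups", [[[1.0]], [[1.0], []], [[1.0], [2.0]]]
    )
    def test_degenerate_inputs_rejected(self, groups):
        with pytest.raises(ValueError):
            kruskal_wallis(groups)

    def test_null_p_values_are_roughly_uniform(self):
        # quick check; the full 2000-draw calibration runs in the
        # acceptance suite
        rng = np.random.default_rng(6)
        rejections = sum(
            kruskal_wallis(rng.normal(size=(3, 10)))[1] < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.09


def constant_then_diverging_curves(n_runs=8, K=60, k_break=50, noise=0.0):
    """Identical accuracy traces through k_break, run-specific offsets after."""
    rng = np.random.default_rng(0)
    curves = []
    ks = np.arange(1, K + 1)
    base = 0.5 + 0.004 * ks
    for run in range(n_runs):
        metric = base.copy()
        metric[ks > k_break] += 0.01 * run
        if noise:
            metric = metric + rng.normal(0, noise, size=K)
        curves.append(
            AccumulationCurve(
                ks, np.clip(metric, 0, 1), np.zeros(K), np.zeros(K),
                metric_name="accuracy", model_kind="nn", run_seed=run,
            )
        )
    return curves


class TestTurningPoint:
    def test_detects_break_after_constructed_divergence(self):
        curves = constant_then_diverging_curves()
        result = turning_point(curves, alpha=0.1, window=10)
        assert result.found
        assert 50 <= result.k_star < 60
        assert (result.p_trace.loc[:50] == 1.0).all()

    def test_identical_runs_never_diverge(self):
        curves = constant_then_diverging_curves(n_runs=4, k_break=60)
        result = turning_point(curves, alpha=0.1, window=10)
        assert result.found
        assert result.k_star == 60
        assert result.mean_accuracy_at_k_star == pytest.approx(
            curves[0].metric[-1]
        )

    def test_alpha_one_flags_not_found_on_noisy_curves(self):
        curves = constant_then_diverging_curves(noise=1e-4)
        result = turning_point(curves, alpha=1.0, window=10)
        assert not result.found
        assert result.k_star is None
        assert result.mean_accuracy_at_k_star is None

    def test_monotone_in_alpha(self):
        curves = constant_then_diverging_curves(noise=5e-3)
        k_stars = []
        for alpha in (0.01, 0.1, 0.5):
            r = turning_point(curves, alpha=alpha, window=10)
            k_stars.append(r.k_star if r.k_star is not None else 0)
        assert k_stars[0] >= k_stars[1] >= k_stars[2]

    def test_mismatched_grids_rejected(self):
        a = constant_then_diverging_curves(n_runs=2, K=60)
        b = constant_then_diverging_curves(n_runs=1, K=50)
        with pytest.raises(ValueError, match="grid"):
            turning_point([a[0], b[0]], window=10)

    def test_window_must_fit_grid(self):
        curves = constant_then_diverging_curves(n_runs=2, K=5)
        with pytest.raises(ValueError, match="window"):
            turning_point(curves, window=10)


class TestAccumulationCurve:
    def test_signal_accumulates_on_planted_fixture(self, planted_cohort,
                                                   planted_panel,
                                                   planted_split):
        matrix, labels, truth = planted_cohort
        panel, _ = planted_panel
        curve = accumulation_curve(
            panel, matrix, labels, planted_split, K=30,
            seed=3, task="binary", ks=[1, 10, 30],
        )
        assert curve.metric[-1] >= curve.metric[0]
        assert curve.metric[1] > 0.9  # 10 planted markers separate well

    def test_single_point_curve(self, planted_cohort, planted_panel,
                                planted_split):
        matrix, labels, _ = planted_cohort
        panel, _ = planted_panel
        curve = accumulation_curve(panel, matrix, labels, planted_split,
                                   K=1, seed=0)
        assert len(curve.ks) == 1

    def test_noise_cohort_auc_band(self, noise_cohort):
        matrix, labels, _ = noise_cohort
        panel = MarkerPanel.from_scores(
            {f: 1.0 for f in matrix.feature_ids[:15]}
        )
        split = split_samples(matrix.n_samples, seed=1)
        curve = accumulation_curve(panel, matrix, labels, split,
                                   K=15, seed=1, ks=[5, 10, 15])
        assert ((curve.metric > 0.3) & (curve.metric < 0.7)).all()

    def test_k_beyond_panel_rejected(self, planted_cohort, planted_panel,
                                     planted_split):
        matrix, labels, _ = planted_cohort
        panel, _ = planted_panel
        with pytest.raises(ValueError, match="exceeds panel"):
            accumulation_curve(panel, matrix, labels, planted_split,
                               K=len(panel) + 1)


class TestCompareModels:
    def test_report_has_three_traces_and_strong_signal_everywhere(
        self, planted_cohort, planted_panel, planted_split
    ):
        matrix, labels, _ = planted_cohort
        panel, _ = planted_panel
        report = compare_models(
            panel, matrix, labels, planted_split, seed=3,
            ks=[5, 10, 15, 20],
        )
        assert set(report.curves) == {"nn", "random_forest", "decision_tree"}
        for kind, curve in report.curves.items():
            assert curve.metric.max() >= 0.9, kind
        assert 0.0 <= report.kw_p <= 1.0

    def test_no_model_stands_out_on_noise(self, noise_cohort):
        matrix, labels, _ = noise_cohort
        panel = MarkerPanel.from_scores(
            {f: 1.0 for f in matrix.feature_ids[:12]}
        )
        hits = 0
        for seed in range(5):
            split = split_samples(matrix.n_samples, seed=seed)
            report = compare_models(panel, matrix, labels, split,
                                    seed=seed, ks=[4, 8, 12])
            if report.kw_p > 0.05:
                hits += 1
        assert hits >= 4
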