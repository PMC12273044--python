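"""Panel assembly, logistic scoring, ROC/AUC, bootstrap CI, forest check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hoxscape import simulate
from hoxscape.biomarker import (
    PanelMatrix,
    auc_mann_whitney,
    bootstrap_ci,
    build_panel,
    evaluate_panel,
    fit_logistic,
    forest_check,
    roc_auc,
)

PANEL = [("chr17", p) for p in simulate.PANEL_LOCI]


def panel_from(values, labels, contrast=("PMOL", "TN0plus")):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    df = pd.DataFrame(values, columns=[f"chr1:{i}" for i in range(values.shape[1])])
    return PanelMatrix(values=df, labels=np.asarray(labels), contrast=contrast)


def concordance_oracle(scores, labels):
    """Brute force over all positive-negative pairs; ties count half."""
    s = np.asarray(scores, dtype=float)
    pos, neg = s[np.asarray(labels) == 1], s[np.asarray(labels) == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestBuildPanel:
    def test_worked_cohort_panel_shape_and_labels(self, coverage, bundle):
        m = build_panel(coverage, bundle.metadata, PANEL, ("PMOL", "TN0plus"))
        assert m.values.shape == (16, 8)
        assert m.labels.sum() == 8 and (m.labels == 0).sum() == 8

    def test_sample_missing_a_locus_is_dropped(self, coverage, bundle):
        cov = dict(coverage)
        sid = "P01_T"
        df = cov[sid]
        cov[sid] = df[~((df["chrom"] == "chr17") & (df["pos"] == simulate.PANEL_LOCI[0]))]
        m = build_panel(cov, bundle.metadata, PANEL, ("PMOL", "TN0plus"))
        assert m.values.shape == (15, 8)
        assert "P01" not in m.values.index

    def test_unknown_group_name_raises(self, coverage, bundle):
        with pytest.raises(ValueError, match="unknown group"):
            build_panel(coverage, bundle.metadata, PANEL, ("PMOL", "NOT_A_GROUP"))

    def test_histology_contrast_supported(self, coverage, bundle):
        m = build_panel(coverage, bundle.metadata, PANEL, ("leukoplakia", "MDSCC"))
        assert (m.labels == 0).sum() == 3 and (m.labels == 1).sum() == 5

    def test_raw_tumor_mode_uses_tumor_values(self, coverage, bundle):
        m = build_panel(coverage, bundle.metadata, PANEL, ("PMOL", "TN0plus"),
                        mode="raw_tumor")
        assert set(m.values.index) <= set(bundle.metadata["sample_id"])
        assert (m.values.to_numpy() >= 0).all()


class TestLogistic:
    def test_mean_score_equals_prevalence(self):
        """ML logistic with intercept balances scores at the class prevalence
        (the intercept-only closed form log(p/(1-p)) generalized)."""
        rng = np.random.default_rng(17)
        labels = np.array([1, 0, 0, 0] * 3)
        feature = rng.normal(size=12) * 0.1  # weak, keeps the fit regular
        scores = fit_logistic(panel_from(feature, labels))
        assert scores.mean() == pytest.approx(0.25, abs=1e-4)

    def test_uninformative_scores_are_null_under_label_permutation(self):
        """Permutation null: scores fixed, labels shuffled -> mean AUC ~ 0.5
        over 100 replicates (the score cannot adapt its sign to the labels)."""
        rng = np.random.default_rng(0)
        labels = np.array([0] * 10 + [1] * 10)
        feature = rng.normal(size=20)  # independent of labels
        scores = fit_logistic(panel_from(feature, labels))
        aucs = []
        for _ in range(100):
            permuted = rng.permutation(labels)
            aucs.append(roc_auc(scores, permuted).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_perfect_separation_falls_back_to_feature_order(self):
        feature = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        scores = fit_logistic(panel_from(feature, labels))
        assert np.all(np.argsort(scores) == np.argsort(feature))
        assert roc_auc(scores, labels).auc == 1.0

    def test_requires_three_per_class(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_logistic(panel_from([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1]))


class TestROC:
    def test_perfect_separation_auc_one(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0
        assert res.points[0] == (0.0, 0.0) and res.points[-1] == (1.0, 1.0)

    def test_all_scores_tied_auc_half(self):
        assert roc_auc([0.5] * 8, [0, 1] * 4).auc == pytest.approx(0.5)

    def test_interleaved_example_three_of_four_concordant(self):
        res = roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert res.auc == pytest.approx(0.75)
        assert concordance_oracle([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_curve_is_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(4)
        res = roc_auc(rng.normal(size=30), rng.integers(0, 2, size=30) | (np.arange(30) == 0))
        xs, ys = zip(*res.points)
        assert all(b >= a for a, b in zip(xs, xs[1:]))
        assert all(b >= a for a, b in zip(ys, ys[1:]))

    def test_matches_pairwise_concordance_oracle_on_random_instances(self):
        """Trapezoid AUC == exhaustive pair concordance, 500 small cases."""
        rng = np.random.default_rng(1)
        for _ in range(500):
            n = int(rng.integers(4, 13))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            scores = np.round(rng.normal(size=n), 1)  # coarse -> frequent ties
            res = roc_auc(scores, labels)
            assert res.auc == pytest.approx(concordance_oracle(scores, labels), abs=1e-12)
            assert res.auc == pytest.approx(auc_mann_whitney(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        for _ in range(50):
            labels = rng.integers(0, 2, size=40)
            if labels.sum() in (0, 40):
                continue
            scores = rng.normal(size=40)
            assert roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    @given(
        st.lists(st.floats(-5, 5), min_size=6, max_size=20),
        st.floats(0.1, 3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, raw, slope):
        # round so exp() stays injective on the realized values
        scores = np.round(np.asarray(raw), 3)
        labels = (np.arange(len(scores)) % 2).astype(int)
        transformed = np.exp(slope * scores)
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc(transformed, labels).auc, abs=1e-12
        )

    def test_label_reversal_maps_auc_to_complement(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=24)
        labels = rng.integers(0, 2, size=24)
        labels[0], labels[1] = 0, 1
        a = roc_auc(scores, labels).auc
        b = roc_auc(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestBootstrap:
    def test_same_seed_reproduces_ci(self):
        rng = np.random.default_rng(3)
        scores, labels = rng.normal(size=20), np.array([0, 1] * 10)
        assert bootstrap_ci(scores, labels, seed=7) == bootstrap_ci(scores, labels, seed=7)

    def test_perfectly_separated_panel_ci_low_high(self):
        scores = np.r_[np.zeros(8), np.ones(8)]
        labels = np.r_[np.zeros(8, int), np.ones(8, int)]
        lo, hi = bootstrap_ci(scores, labels, seed=0)
        assert lo >= 0.9 and hi == 1.0

    def test_null_ci_covers_half_in_most_seeds(self):
        """Permuted labels: 95% CI contains 0.5 in >= 90 of 100 seeds."""
        rng = np.random.default_rng(12)
        scores = rng.normal(size=16)
        covered = 0
        for seed in range(100):
            labels = np.array([0] * 8 + [1] * 8)
            rng.shuffle(labels)
            lo, hi = bootstrap_ci(scores, labels, n_boot=500, seed=seed)
            covered += lo <= 0.5 <= hi
        assert covered >= 90

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)

        def width(n):
            half = n // 2
            scores = np.r_[rng.normal(0, 1, half), rng.normal(1, 1, half)]
            labels = np.r_[np.zeros(half, int), np.ones(half, int)]
            lo, hi = bootstrap_ci(scores, labels, seed=1)
            return hi - lo

        assert width(160) < width(16)

    def test_percentile_bounds_bracket_point_auc(self, coverage, bundle):
        m = build_panel(coverage, bundle.metadata, PANEL, ("PMOL", "TN0plus"))
        res = evaluate_panel(m, seed=3)
        assert res.ci_low <= res.auc <= res.ci_high


class TestForest:
    def synth_panel(self, rng, mean0, mean1, n=8, sd=5.0):
        values = np.r_[
            rng.normal(mean0, sd, size=(n, 8)), rng.normal(mean1, sd, size=(n, 8))
        ]
        labels = np.r_[np.zeros(n, int), np.ones(n, int)]
        return panel_from(values, labels)

    def test_strong_separation_high_oob_auc(self):
        rng = np.random.default_rng(21)
        m = self.synth_panel(rng, 5.0, 60.0)
        assert forest_check(m, seed=0) >= 0.95

    def test_permuted_labels_near_null(self):
        """OOB AUC over 50 label permutations: mean within 0.05 of 0.5.

        Run at n=50 per class: out-of-bag probabilities carry a small
        pessimistic bias from in-bag class composition that only vanishes
        with sample size.
        """
        rng = np.random.default_rng(22)
        values = rng.normal(30, 10, size=(100, 8))
        aucs = []
        for seed in range(50):
            labels = np.array([0] * 50 + [1] * 50)
            rng.shuffle(labels)
            m = panel_from(values, labels)
            aucs.append(forest_check(m, n_trees=100, seed=seed))
        assert abs(np.mean(aucs) - 0.5) < 0.05
        assert all(0.3 <= a <= 0.7 for a in aucs)

    def test_constant_feature_gives_chance_auc(self):
        m = panel_from(np.ones((12, 1)), np.array([0, 1] * 6))
        assert forest_check(m, seed=0) == pytest.approx(0.5)
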