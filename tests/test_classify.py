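"""Kernels, fusion, metrics and the nested cross-validation protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hiernet.classify import (
    CVConfig,
    compute_metrics,
    frequency_table,
    fuse_kernels,
    nested_cv,
    rbf_kernel,
)


def toy_blocks(n_per_group=10, n_features=12, separation=0.0, seed=0):
    """Small two-block feature set with optional separation in block one."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    y = np.r_[np.ones(n_per_group), np.zeros(n_per_group)]
    roi = rng.normal(size=(n, n_features))
    roi[:, :3] += separation * y[:, None]
    net = rng.normal(size=(n, n_features))
    ids = [f"S{i:03d}" for i in range(n)]
    blocks = {
        "roi_L4": pd.DataFrame(roi, index=ids, columns=[f"roi_L4|{j:02d}|gm_volume" for j in range(1, n_features + 1)]),
        "net_all": pd.DataFrame(net, index=ids, columns=[f"net_L4|{j:02d}-{j + 1:02d}" for j in range(1, n_features + 1)]),
    }
    labels = ["high" if v else "low" for v in y]
    return blocks, labels


class TestRbfKernel:
    def test_identical_subjects_give_one(self):
        X = np.tile([1.0, 2.0, 3.0], (2, 1))
        K = rbf_kernel(X, gamma=0.7)
        assert K[0, 1] == pytest.approx(1.0)

    def test_gamma_zero_limit(self):
        X = np.random.default_rng(0).normal(size=(4, 3))
        np.testing.assert_allclose(rbf_kernel(X, gamma=1e-12), 1.0, atol=1e-9)

    def test_hand_computed_distances(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        K = rbf_kernel(X, gamma=0.5)
        assert K[0, 1] == pytest.approx(np.exp(-0.5 * 1.0))
        assert K[0, 2] == pytest.approx(np.exp(-0.5 * 4.0))
        assert K[1, 2] == pytest.approx(np.exp(-0.5 * 5.0))

    def test_psd_and_unit_diagonal(self):
        X = np.random.default_rng(1).normal(size=(6, 4))
        K = rbf_kernel(X, gamma=0.3)
        np.testing.assert_allclose(np.diag(K), 1.0)
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_non_finite_rejected(self):
        X = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError, match="non-finite"):
            rbf_kernel(X, gamma=1.0)


class TestFusion:
    def test_endpoints(self):
        a = np.array([[1.0, 0.2], [0.2, 1.0]])
        b = np.array([[1.0, 0.8], [0.8, 1.0]])
        np.testing.assert_array_equal(fuse_kernels(a, b, 1.0), a)
        np.testing.assert_array_equal(fuse_kernels(a, b, 0.0), b)

    def test_halfway_is_elementwise_average(self):
        a = np.array([[1.0, 0.2], [0.2, 1.0]])
        b = np.array([[1.0, 0.8], [0.8, 1.0]])
        np.testing.assert_allclose(fuse_kernels(a, b, 0.5), (a + b) / 2)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_kernels(np.eye(2), np.eye(3), 0.5)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            fuse_kernels(np.eye(2), np.eye(2), 1.5)


class TestMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics(["high", "low"] * 5, ["high", "low"] * 5, np.r_[np.ones(5), np.zeros(5)][[0, 5, 1, 6, 2, 7, 3, 8, 4, 9]])
        assert m.acc == m.sen == m.spe == 1.0
        assert m.youden == pytest.approx(1.0)

    def test_all_positive_predictions(self):
        y = ["high"] * 5 + ["low"] * 5
        m = compute_metrics(y, ["high"] * 10)
        assert m.acc == 0.5
        assert m.sen == 1.0
        assert m.spe == 0.0
        assert m.youden == pytest.approx(0.0)
        assert m.bac == pytest.approx(0.5)

    def test_hand_built_confusion_table(self):
        # 10 subjects: TP=3, FN=2, TN=4, FP=1
        y_true = ["high"] * 5 + ["low"] * 5
        y_pred = ["high"] * 3 + ["low"] * 2 + ["low"] * 4 + ["high"]
        m = compute_metrics(y_true, y_pred)
        assert m.acc == pytest.approx(0.7)
        assert m.sen == pytest.approx(3 / 5)
        assert m.spe == pytest.approx(4 / 5)
        precision = 3 / 4
        assert m.f_score == pytest.approx(2 * precision * 0.6 / (precision + 0.6))
        assert m.youden == pytest.approx(0.6 + 0.8 - 1)
        assert m.bac == pytest.approx(0.7)

    def test_single_class_truth_flagged(self):
        with pytest.warns(UserWarning, match="single-class"):
            m = compute_metrics(["high"] * 4, ["high", "low"] * 2)
        assert np.isnan(m.spe)

    @given(
        tp=st.integers(0, 20), fn=st.integers(0, 20),
        tn=st.integers(0, 20), fp=st.integers(0, 20),
    )
    def test_metric_identities(self, tp, fn, tn, fp):
        if tp + fn == 0 or tn + fp == 0:
            return
        y_true = ["high"] * (tp + fn) + ["low"] * (tn + fp)
        y_pred = ["high"] * tp + ["low"] * fn + ["low"] * tn + ["high"] * fp
        m = compute_metrics(y_true, y_pred)
        assert m.youden == pytest.approx(m.sen + m.spe - 1)
        assert m.bac == pytest.approx((m.sen + m.spe) / 2)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        y = ["high"] * 8 + ["low"] * 8
        scores = rng.normal(size=16)
        base = compute_metrics(y, y, scores).auc
        warped = compute_metrics(y, y, np.exp(3 * scores) + 7).auc
        assert base == pytest.approx(warped)


class TestNestedCV:
    def test_separable_cohort_is_perfect(self):
        blocks, labels = toy_blocks(n_per_group=8, separation=8.0, seed=1)
        report = nested_cv(blocks, labels, CVConfig(repetitions=3, inner_folds=3), seed=0)
        assert report.metrics_mean.acc >= 0.95

    def test_permuted_labels_are_chance(self):
        blocks, labels = toy_blocks(n_per_group=10, separation=6.0, seed=2)
        rng = np.random.default_rng(0)
        permuted = list(rng.permutation(labels))
        report = nested_cv(blocks, permuted, CVConfig(repetitions=15, inner_folds=3), seed=0)
        assert abs(report.metrics_mean.acc - 0.5) <= 0.12

    def test_each_subject_tested_once_per_repetition(self):
        blocks, labels = toy_blocks(n_per_group=6, separation=3.0, seed=3)
        report = nested_cv(blocks, labels, CVConfig(repetitions=2, inner_folds=2), seed=1)
        for rep in range(2):
            tested = [i for f in report.folds if f.repetition == rep for i in f.test_ids]
            assert sorted(tested) == sorted(blocks["roi_L4"].index)

    def test_frequencies_bounded_by_fold_fits(self):
        blocks, labels = toy_blocks(n_per_group=6, separation=3.0, seed=4)
        report = nested_cv(blocks, labels, CVConfig(repetitions=3, inner_folds=2), seed=2)
        bound = 3 * 2
        for counter in report.frequencies.values():
            assert counter and max(counter.values()) <= bound

    def test_same_seed_reproduces_report(self):
        blocks, labels = toy_blocks(n_per_group=6, separation=2.0, seed=5)
        cfg = CVConfig(repetitions=2, inner_folds=2)
        a = nested_cv(blocks, labels, cfg, seed=3)
        b = nested_cv(blocks, labels, cfg, seed=3)
        assert a.to_dict() == b.to_dict()

    def test_beta_endpoints_reproduce_single_kernel(self):
        blocks, labels = toy_blocks(n_per_group=8, separation=2.0, seed=6)
        cfg_kwargs = dict(repetitions=2, inner_folds=2, c_grid=(1.0,))
        fused_roi = nested_cv(blocks, labels, CVConfig(fixed_beta=1.0, **cfg_kwargs), seed=4)
        roi_only = nested_cv(blocks, labels, CVConfig(net_block=None, **cfg_kwargs), seed=4)
        for a, b in zip(fused_roi.folds, roi_only.folds):
            np.testing.assert_array_equal(a.y_pred, b.y_pred)
        fused_net = nested_cv(blocks, labels, CVConfig(fixed_beta=0.0, **cfg_kwargs), seed=4)
        net_only = nested_cv(blocks, labels, CVConfig(roi_block=None, **cfg_kwargs), seed=4)
        for a, b in zip(fused_net.folds, net_only.folds):
            np.testing.assert_array_equal(a.y_pred, b.y_pred)

    def test_too_few_subjects_rejected(self):
        blocks, labels = toy_blocks(n_per_group=3)
        with pytest.raises(ValueError, match="per group"):
            nested_cv(blocks, labels, CVConfig(repetitions=1), seed=0)


class TestBaselines:
    def test_separable_cohort_beats_chance_everywhere(self):
        from hiernet.classify import baseline_classifiers

        blocks, labels = toy_blocks(n_per_group=8, separation=8.0, seed=10)
        table = baseline_classifiers(
            blocks, labels, CVConfig(repetitions=2, inner_folds=2), seed=0
        )
        assert set(table.index) == {
            "svm_rbf", "svm_linear", "knn", "naive_bayes", "decision_tree",
        }
        assert (table["accuracy_mean"] >= 0.8).all()

    def test_single_requested_baseline(self):
        from sklearn.naive_bayes import GaussianNB

        from hiernet.classify import baseline_classifiers

        blocks, labels = toy_blocks(n_per_group=6, separation=4.0, seed=11)
        table = baseline_classifiers(
            blocks, labels, CVConfig(repetitions=1, inner_folds=2), seed=0,
            classifiers={"naive_bayes": GaussianNB()},
        )
        assert list(table.index) == ["naive_bayes"]


class TestFrequencyTable:
    def test_ranked_and_annotated(self, atlas):
        blocks, labels = toy_blocks(n_per_group=8, separation=5.0, seed=7)
        report = nested_cv(blocks, labels, CVConfig(repetitions=2, inner_folds=2), seed=5)
        table = frequency_table(report, atlas, top_k=5, role="roi")
        assert list(table["frequency"]) == sorted(table["frequency"], reverse=True)
        assert {"roi", "hemisphere", "measure"} <= set(table.columns)

    def test_top_k_larger_than_table(self):
        blocks, labels = toy_blocks(n_per_group=8, separation=5.0, seed=8)
        report = nested_cv(blocks, labels, CVConfig(repetitions=1, inner_folds=2), seed=6)
        table = frequency_table(report, top_k=10_000, role="net")
        assert len(table) == len(report.frequencies["net"])

    def test_same_seed_gives_identical_tables(self):
        blocks, labels = toy_blocks(n_per_group=8, separation=4.0, seed=9)
        cfg = CVConfig(repetitions=2, inner_folds=2)
        a = frequency_table(nested_cv(blocks, labels, cfg, seed=7), top_k=10, role="roi")
        b = frequency_table(nested_cv(blocks, labels, cfg, seed=7), top_k=10, role="roi")
        pd.testing.assert_frame_equal(a, b)
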