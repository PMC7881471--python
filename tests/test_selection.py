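"""Selection cascade: t-test screen, mRMR ranking, SVM-RFE, composition."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hiernet.selection import (
    SelectionConfig,
    SelectionError,
    discretize,
    mrmr_rank,
    mutual_information,
    run_cascade,
    svm_rfe,
    ttest_filter,
)


def frame(arr, names=None):
    arr = np.asarray(arr, float)
    names = names or [f"f{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=names)


class TestTTestFilter:
    def test_constant_feature_removed(self):
        X = frame(np.column_stack([np.ones(8), np.r_[np.zeros(4), np.ones(4)]]))
        y = ["high"] * 4 + ["low"] * 4
        survivors, stats = ttest_filter(X, y, alpha=0.05)
        assert "f0" not in survivors
        assert stats.loc["f0", "p"] == 1.0

    def test_overwhelming_separation_retained(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(10.0, 1.0, 10)
        X = frame(np.r_[a, b][:, None])
        survivors, _ = ttest_filter(X, ["high"] * 10 + ["low"] * 10, alpha=0.05)
        assert survivors == ["f0"]

    def test_matches_textbook_computation(self):
        # pooled-variance two-sample t on a 6-subject toy, by hand
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        X = frame(np.r_[a, b][:, None])
        _, stats = ttest_filter(X, ["high"] * 3 + ["low"] * 3, alpha=0.05)
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert stats.loc["f0", "t"] == pytest.approx(t_hand)

    def test_single_group_rejected(self):
        X = frame(np.ones((4, 1)))
        with pytest.raises(SelectionError):
            ttest_filter(X, ["high"] * 4, alpha=0.05)


def _mid_oracle(D, yb, keep, names):
    """Exhaustive greedy MID: re-evaluate the objective at every step."""
    chosen: list[int] = []
    remaining = list(range(D.shape[1]))
    rel = {j: mutual_information(yb, D[:, [j]])[0] for j in remaining}
    while len(chosen) < keep:
        best, best_key = None, None
        for j in remaining:
            if chosen:
                red = np.mean([mutual_information(D[:, c], D[:, [j]])[0] for c in chosen])
            else:
                red = 0.0
            key = (rel[j] - red, names[j])
            # max score, lexically smaller name on ties
            if best_key is None or key[0] > best_key[0] + 1e-12 or (
                abs(key[0] - best_key[0]) <= 1e-12 and key[1] < best_key[1]
            ):
                best, best_key = j, key
        chosen.append(best)
        remaining.remove(best)
    return [names[j] for j in chosen]


class TestMrmr:
    def test_duplicate_ranked_below_independent(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.zeros(12), np.ones(12)]
        informative = y + rng.normal(0, 0.3, 24)
        other = y + rng.normal(0, 0.3, 24)
        X = frame(
            np.column_stack([informative, informative, other]),
            ["dup_a", "dup_b", "indep"],
        )
        ranked = mrmr_rank(X, ["high" if v else "low" for v in y], keep=3)
        # one duplicate leads, the independent feature beats the other copy
        assert ranked.index("indep") < max(ranked.index("dup_a"), ranked.index("dup_b"))

    def test_single_candidate(self):
        X = frame(np.arange(8.0)[:, None], ["only"])
        assert mrmr_rank(X, ["high"] * 4 + ["low"] * 4, keep=1) == ["only"]

    def test_keep_larger_than_pool_warns(self):
        X = frame(np.random.default_rng(0).normal(size=(8, 2)))
        with pytest.warns(UserWarning, match="keeping all"):
            ranked = mrmr_rank(X, ["high"] * 4 + ["low"] * 4, keep=5)
        assert len(ranked) == 2

    def test_matches_bruteforce_greedy(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.zeros(6), np.ones(6)]
        X = frame(rng.normal(size=(12, 4)) + y[:, None] * rng.uniform(0, 2, 4))
        labels = ["high" if v else "low" for v in y]
        ranked = mrmr_rank(X, labels, keep=4)
        D = discretize(X)
        yb = (np.asarray(labels) == "low").astype(int)  # matches _as_binary ordering
        assert ranked == _mid_oracle(D, yb, 4, list(X.columns))


class TestSvmRfe:
    def test_perfect_feature_survives(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.zeros(10), np.ones(10)]
        X = frame(np.column_stack([y * 4 - 2] + [rng.normal(size=20) for _ in range(6)]))
        labels = ["high" if v else "low" for v in y]
        selected, _ = svm_rfe(X, labels, keep=2, step=1)
        assert "f0" in selected

    def test_keep_everything_is_identity(self):
        X = frame(np.random.default_rng(0).normal(size=(10, 5)))
        labels = ["high"] * 5 + ["low"] * 5
        selected, eliminated = svm_rfe(X, labels, keep=5)
        assert selected == list(X.columns)
        assert eliminated == []

    def test_elimination_matches_stepwise_oracle(self):
        # re-run the scoring by hand at each iteration
        from sklearn.svm import SVC

        rng = np.random.default_rng(5)
        y = np.r_[np.zeros(9), np.ones(9)]
        X = frame(rng.normal(size=(18, 5)) + y[:, None] * rng.uniform(0.2, 1.5, 5))
        labels = ["high" if v else "low" for v in y]
        _, eliminated = svm_rfe(X, labels, keep=1, step=1)

        names = list(X.columns)
        cols = list(range(5))
        yb = (np.asarray(labels) == "low").astype(int)
        expected = []
        while len(cols) > 1:
            vals = X.to_numpy()[:, cols]
            z = (vals - vals.mean(0)) / vals.std(0)
            w2 = SVC(kernel="linear", C=1.0).fit(z, yb).coef_.ravel() ** 2
            worst = min(range(len(cols)), key=lambda k: (w2[k], tuple(-ord(c) for c in names[cols[k]])))
            expected.append(names[cols[worst]])
            del cols[worst]
        assert eliminated == expected

    def test_agrees_with_sklearn_rfe(self):
        # independent cross-check: sklearn's RFE on pre-standardized data
        from sklearn.feature_selection import RFE
        from sklearn.svm import SVC

        rng = np.random.default_rng(8)
        y = np.r_[np.zeros(12), np.ones(12)]
        vals = rng.normal(size=(24, 6)) + y[:, None] * rng.uniform(0.1, 2.0, 6)
        z = (vals - vals.mean(0)) / vals.std(0)
        X = frame(z)
        labels = ["high" if v else "low" for v in y]
        selected, _ = svm_rfe(X, labels, keep=3, step=1)
        ref = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=3, step=1).fit(
            z, (np.asarray(labels) == "low").astype(int)
        )
        assert set(selected) == set(np.array(X.columns)[ref.support_])


class TestCascade:
    def test_nestedness(self, null_cohort, atlas):
        from hiernet.features import assemble_blocks

        blocks = assemble_blocks(atlas, null_cohort.subjects)
        X = blocks["roi_L4"]
        labels = null_cohort.labels
        selected, trace = run_cascade(X, labels, SelectionConfig(rfe_keep=5, rfe_grid=(5,)))
        assert set(selected) <= set(trace.mrmr_ranking)
        assert set(trace.mrmr_ranking) <= set(trace.ttest_survivors)
        assert set(trace.ttest_survivors) <= set(X.columns)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.zeros(12), np.ones(12)]
        X = frame(rng.normal(size=(24, 30)) + y[:, None] * np.r_[np.full(3, 1.5), np.zeros(27)])
        labels = ["high" if v else "low" for v in y]
        cfg = SelectionConfig(mrmr_keep=10, rfe_keep=4)
        a, ta = run_cascade(X, labels, cfg)
        b, tb = run_cascade(X, labels, cfg)
        assert a == b
        assert ta.mrmr_ranking == tb.mrmr_ranking
        assert ta.rfe_elimination == tb.rfe_elimination

    def test_all_noise_at_tiny_alpha_errors(self):
        rng = np.random.default_rng(6)
        X = frame(rng.normal(size=(16, 20)))
        labels = ["high"] * 8 + ["low"] * 8
        with pytest.raises(SelectionError, match="alpha"):
            run_cascade(X, labels, SelectionConfig(alpha=1e-9))

    def test_planted_features_dominate(self):
        rng = np.random.default_rng(9)
        y = np.r_[np.zeros(17), np.ones(17)]
        signal = y[:, None] * 2.0 + rng.normal(size=(34, 4))
        noise = rng.normal(size=(34, 60))
        X = frame(np.column_stack([signal, noise]))
        labels = ["high" if v else "low" for v in y]
        selected, _ = run_cascade(X, labels, SelectionConfig(rfe_keep=6, rfe_grid=(6,)))
        assert len(set(selected) & {"f0", "f1", "f2", "f3"}) >= 3

    def test_invalid_config_rejected(self):
        with pytest.raises(SelectionError):
            SelectionConfig(alpha=1.5)
        with pytest.raises(SelectionError):
            SelectionConfig(mrmr_keep=5, rfe_keep=10)
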