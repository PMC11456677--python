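"""Fisher-score ranking, LOOCV linear SVM, ROC/AUC, permutation inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.svm import SVC

from cbtc.classify import (
    _rank,
    _standardize,
    accuracy_curve,
    fisher_score,
    loocv_svm,
    permutation_test_auc,
    roc_auc,
)


def auc_bruteforce(decisions, labels):
    """Independent oracle: concordant-pair counting with half-weight ties."""
    pos = decisions[labels == 1]
    neg = decisions[labels == -1]
    total = 0.0
    for p in pos:
        for n in neg:
            total += (p > n) + 0.5 * (p == n)
    return total / (len(pos) * len(neg))


def separable_data(n_per_class=20, m=6, seed=0):
    """Linearly separable classes: feature 0 carries a guaranteed margin of 4."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((2 * n_per_class, m))
    y = np.array([1] * n_per_class + [-1] * n_per_class)
    x[:, 0] = y * (2.0 + np.abs(rng.standard_normal(2 * n_per_class)))
    return x, y


class TestFisherScore:
    def test_equal_class_means_score_zero(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        y = np.array([1, 1, 1, -1, -1, -1])
        assert fisher_score(x, y) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        x = np.array([3.0, 4.0, 5.0, 0.0, 1.0, 2.0])
        y = np.array([1, 1, 1, -1, -1, -1])
        assert fisher_score(x, y) == pytest.approx(2.25)

    def test_decreases_with_within_class_noise(self):
        y = np.array([1] * 10 + [-1] * 10)
        rng = np.random.default_rng(2)
        scores = []
        for sd in (0.01, 0.1, 1.0):
            x = np.r_[2 + sd * rng.standard_normal(10), sd * rng.standard_normal(10)]
            scores.append(fisher_score(x, y))
        assert scores[0] > scores[1] > scores[2]

    def test_zero_variance_separated_means_is_inf(self):
        x = np.array([2.0, 2.0, 0.0, 0.0])
        y = np.array([1, 1, -1, -1])
        assert fisher_score(x, y) == np.inf

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fisher_score(np.ones(3), np.array([1, 1, 1]))


class TestRocAuc:
    def test_perfect_ranking(self):
        (_, _), auc = roc_auc([0.9, 0.8, 0.7, 0.1], np.array([1, 1, -1, -1]))
        assert auc == 1.0

    def test_hand_value(self):
        (_, _), auc = roc_auc([0.9, 0.4, 0.6, 0.1], np.array([1, 1, -1, -1]))
        assert auc == pytest.approx(0.75)

    def test_total_ties_are_chance(self):
        (_, _), auc = roc_auc([0.5, 0.5, 0.5, 0.5], np.array([1, 1, -1, -1]))
        assert auc == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(1, 4), st.integers(1, 4), st.integers(0, 2 ** 31 - 1))
    def test_matches_bruteforce_pair_counting(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(seed)
        labels = np.array([1] * n_pos + [-1] * n_neg)
        decisions = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=n_pos + n_neg)
        (_, _), auc = roc_auc(decisions, labels)
        assert auc == pytest.approx(auc_bruteforce(decisions, labels), abs=1e-12)


class TestLoocvSvm:
    def test_separable_classes_classified_perfectly(self):
        x, y = separable_data()
        preds, _ = loocv_svm(x, y, k=x.shape[1])
        assert (preds == y).all()

    def test_label_flip_symmetry(self):
        x, y = separable_data(n_per_class=8, seed=1)
        preds, dec = loocv_svm(x, y, k=3)
        preds_f, dec_f = loocv_svm(x, -y, k=3)
        np.testing.assert_array_equal(preds_f, -preds)
        # equality up to the solver tolerance of the underlying QP
        np.testing.assert_allclose(dec_f, -dec, atol=5e-3)

    def test_fold_artifacts_use_training_subjects_only(self):
        # dual-route check: recompute fold 0 by hand from the 1..n-1 rows
        x, y = separable_data(n_per_class=6, m=5, seed=2)
        k = 3
        _, dec = loocv_svm(x, y, k=k, ranking_scope="fold")
        xt, yt = x[1:], y[1:]
        order = _rank(xt, yt)[:k]
        xtr, xte = _standardize(xt[:, order], x[:1, order])
        clf = SVC(kernel="linear", C=1.0).fit(xtr, yt)
        assert dec[0] == pytest.approx(clf.decision_function(xte)[0], abs=1e-10)
        # and perturbing the held-out row leaves other folds' decisions intact
        x2 = x.copy()
        x2[0] += 100.0
        _, dec2 = loocv_svm(x2, y, k=k, ranking_scope="fold")
        # fold 0's own decision shifts, but all folds that trained on row 0
        # change only through that row's training contribution; verify fold 0
        # artifacts ignored it by recomputing with the clean training rows
        order2 = _rank(x2[1:], y[1:])[:k]
        np.testing.assert_array_equal(order, order2)

    def test_k_bounds_checked(self):
        x, y = separable_data(n_per_class=4)
        with pytest.raises(ValueError):
            loocv_svm(x, y, k=x.shape[1] + 1)


class TestAccuracyCurve:
    def test_contract_shape_and_range(self):
        x, y = separable_data(n_per_class=8, m=5, seed=3)
        res = accuracy_curve(x, y)
        assert sorted(res.accuracy_by_k) == list(range(1, 6))
        assert all(0 <= a <= 1 for a in res.accuracy_by_k.values())
        assert res.accuracy == res.accuracy_by_k[res.best_k]
        assert 0 <= res.auc <= 1

    def test_smallest_k_wins_ties(self):
        x, y = separable_data(n_per_class=10, m=4, seed=4)
        res = accuracy_curve(x, y)
        best = res.accuracy
        ks = [k for k, a in res.accuracy_by_k.items() if a == best]
        assert res.best_k == min(ks)

    def test_sensitivity_specificity_decomposition(self):
        x, y = separable_data(n_per_class=10, m=4, seed=5)
        res = accuracy_curve(x, y)
        n_pos = (y == 1).sum()
        acc = (res.sensitivity * n_pos + res.specificity * (len(y) - n_pos)) / len(y)
        assert res.accuracy == pytest.approx(acc)

    def test_global_ranking_mode_runs(self):
        x, y = separable_data(n_per_class=6, m=4, seed=6)
        res = accuracy_curve(x, y, ranking_scope="global")
        assert res.ranking_scope == "global"
        assert res.accuracy == 1.0


class TestPermutationTest:
    def test_deterministic_under_seed(self):
        x, y = separable_data(n_per_class=5, m=4, seed=7)
        p1, null1 = permutation_test_auc(x, y, k=2, n_perm=30, seed=9)
        p2, null2 = permutation_test_auc(x, y, k=2, n_perm=30, seed=9)
        assert p1 == p2
        np.testing.assert_array_equal(null1, null2)

    def test_signal_beats_its_null(self):
        x, y = separable_data(n_per_class=8, m=4, seed=8)
        p, null = permutation_test_auc(x, y, k=2, n_perm=50, seed=10)
        assert p <= 0.02  # observed AUC 1.0 tops the null

    def test_plus_one_variant_never_zero(self):
        x, y = separable_data(n_per_class=5, m=4, seed=9)
        p, _ = permutation_test_auc(x, y, k=2, n_perm=20, seed=11, plus_one=True)
        assert p >= 1 / 21
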