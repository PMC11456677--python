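"""Connectome-based predictive modeling: selection, LOOCV, permutation, stability."""

import numpy as np
import pandas as pd
import pytest

from cbtc.cpm import (
    evaluate_spearman,
    loocv_cpm,
    network_strength,
    permutation_test_cpm,
    run_cpm,
    select_edges,
    well_represented,
)


def noise_fc(n=40, m=15, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.standard_normal((n, m)),
                        columns=[f"e{i}" for i in range(m)])


class TestSelectEdges:
    def test_perfect_copy_is_positive(self):
        fc = noise_fc(seed=1)
        pos, neg = select_edges(fc, fc["e3"].to_numpy())
        assert "e3" in pos and "e3" not in neg

    def test_sign_symmetry(self):
        fc = noise_fc(seed=2)
        pos, neg = select_edges(fc, -fc["e5"].to_numpy())
        assert "e5" in neg and "e5" not in pos

    def test_sets_disjoint(self):
        fc = noise_fc(seed=3)
        y = fc["e0"] - fc["e1"] + np.random.default_rng(4).normal(0, 0.5, len(fc))
        pos, neg = select_edges(fc, y.to_numpy())
        assert not set(pos) & set(neg)

    def test_null_selection_rate_matches_threshold(self):
        rng = np.random.default_rng(5)
        rates = []
        for _ in range(200):
            fc = pd.DataFrame(rng.standard_normal((20, 10)),
                              columns=[f"e{i}" for i in range(10)])
            y = rng.standard_normal(20)
            pos, neg = select_edges(fc, y, p_sel=0.05)
            rates.append((len(pos) + len(neg)) / 10)
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)

    def test_constant_behavior_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            select_edges(noise_fc(), np.ones(40))


class TestNetworkStrength:
    def test_additivity_and_empty(self):
        v = pd.Series({"a": 0.3, "b": 0.5, "c": -0.1})
        assert network_strength(v, []) == 0.0
        assert network_strength(v, ["b"]) == 0.5
        assert network_strength(v, ["a", "b"]) == pytest.approx(0.8)


class TestLoocv:
    def test_planted_linear_signal_recovered(self):
        # small edge family: spurious selections are rare, so the unweighted
        # network-strength sum stays dominated by the planted edge
        rng = np.random.default_rng(0)
        fc = pd.DataFrame(rng.standard_normal((64, 10)),
                          columns=[f"e{i}" for i in range(10)])
        y = 2 * fc["e4"].to_numpy() + rng.normal(0, 0.1, 64)
        res = loocv_cpm(fc, y, mode="positive")
        assert res.spearman_r >= 0.9
        assert all("e4" in sel for sel in res.fold_positive)

    def test_planted_negative_edge_lands_in_negative_sets(self):
        rng = np.random.default_rng(8)
        fc = noise_fc(n=50, m=12, seed=9)
        y = -1.5 * fc["e2"].to_numpy() + rng.normal(0, 0.3, 50)
        res = loocv_cpm(fc, y, mode="negative")
        frac = np.mean([("e2" in sel) for sel in res.fold_negative])
        assert frac >= 0.9
        assert res.spearman_r > 0.7

    def test_combined_two_predictor_and_sum_diff_both_predict(self):
        rng = np.random.default_rng(10)
        fc = noise_fc(n=60, m=10, seed=11)
        y = fc["e0"].to_numpy() - fc["e1"].to_numpy() + rng.normal(0, 0.2, 60)
        for combined in ("two-predictor", "sum-diff"):
            res = loocv_cpm(fc, y, mode="combined", combined=combined)
            assert res.spearman_r > 0.7

    def test_empty_folds_fall_back_to_training_mean(self):
        rng = np.random.default_rng(12)
        fc = noise_fc(n=12, m=3, seed=13)
        y = rng.standard_normal(12)
        res = loocv_cpm(fc, y, mode="positive", p_sel=1e-9)
        assert res.empty_folds == 12
        means = np.array([np.delete(y, i).mean() for i in range(12)])
        np.testing.assert_allclose(res.predicted, means)

    def test_fold_isolation_held_out_behavior_never_enters_selection(self):
        # dual-route: recompute fold 0 selections from the training rows only
        fc = noise_fc(n=20, m=8, seed=14)
        y = 2 * fc["e1"].to_numpy() + np.random.default_rng(15).normal(0, 0.5, 20)
        res = loocv_cpm(fc, y, mode="positive")
        pos0, neg0 = select_edges(fc.iloc[1:], y[1:])
        assert set(res.fold_positive[0]) == set(pos0)
        assert set(res.fold_negative[0]) == set(neg0)
        # changing only subject 0's behavior leaves fold 0's selection unchanged
        y2 = y.copy()
        y2[0] += 50
        res2 = loocv_cpm(fc, y2, mode="positive")
        assert set(res2.fold_positive[0]) == set(pos0)


class TestSpearman:
    def test_monotone_extremes(self):
        assert evaluate_spearman([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0
        assert evaluate_spearman([1, 2, 3, 4], [4, 3, 2, 1]) == -1.0

    def test_hand_value(self):
        assert evaluate_spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            evaluate_spearman([1, 1, 1], [1, 2, 3])


class TestPermutation:
    def test_deterministic_under_seed(self):
        fc = noise_fc(n=20, m=6, seed=16)
        y = np.random.default_rng(17).standard_normal(20)
        p1, null1 = permutation_test_cpm(fc, y, n_perm=40, seed=5)
        p2, null2 = permutation_test_cpm(fc, y, n_perm=40, seed=5)
        assert p1 == p2
        np.testing.assert_array_equal(null1, null2)

    def test_strong_signal_has_small_p(self):
        rng = np.random.default_rng(18)
        fc = noise_fc(n=40, m=10, seed=19)
        y = 2 * fc["e0"].to_numpy() + rng.normal(0, 0.1, 40)
        p, _ = permutation_test_cpm(fc, y, n_perm=200, seed=6)
        assert p < 1 / 100


class TestWellRepresented:
    def test_frequency_thresholding(self):
        folds_pos = [("a", "b"), ("a",), ("a", "c")]
        folds_neg = [("d",), ("d",), ("d",)]
        wr = well_represented(folds_pos, folds_neg, min_frac=1.0)
        assert wr == {"a": "positive", "d": "negative"}
        wr_rel = well_represented(folds_pos, folds_neg, min_frac=0.6)
        assert "b" not in wr_rel and wr_rel["a"] == "positive"

    def test_run_cpm_reports_planted_edges(self):
        rng = np.random.default_rng(20)
        fc = noise_fc(n=64, m=15, seed=21)
        y = 2 * fc["e4"].to_numpy() + rng.normal(0, 0.1, 64)
        out = run_cpm(fc, y, modes=("positive",), min_frac=0.9)
        assert out["positive"].well_represented.get("e4") == "positive"
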