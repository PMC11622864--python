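"""Gain scaling, BIC knee detection, and clustered alpha estimation."""

import math

import numpy as np
import pytest

import pualpha as pa
from pualpha.pulsnar import _merge_small_clusters


class TestScaleByGain:
    def test_unit_gains_identity(self):
        x = np.arange(6.0).reshape(3, 2)
        out = pa.scale_by_gain(x, {"x0": 1.0, "x1": 1.0})
        assert np.array_equal(out, x)

    def test_zero_gain_feature_dropped(self):
        x = np.array([[1.0, 10.0], [2.0, 20.0]])
        out = pa.scale_by_gain(x, {"x0": 2.0, "x1": 0.0})
        assert out.shape == (2, 1)
        assert np.array_equal(out[:, 0], [2.0, 4.0])

    def test_single_feature_scaled(self):
        out = pa.scale_by_gain(np.array([[3.0], [4.0]]), {"x0": 0.5})
        assert np.array_equal(out[:, 0], [1.5, 2.0])

    def test_all_zero_gains_rejected(self):
        with pytest.raises(ValueError):
            pa.scale_by_gain(np.ones((3, 2)), {"x0": 0.0, "x1": 0.0})


def knee_oracle(bic):
    """Exhaustive angle computation over all interior candidates."""
    bic = np.asarray(bic, dtype=float)
    span = bic.max() - bic.min()
    if span == 0:
        return 2
    norm = (bic - bic.min()) / span
    best_bend, best = 0.0, 2
    last = min(int(np.argmin(bic)), len(bic) - 2)
    for i in range(1, last + 1):
        if norm[i - 1] - 2 * norm[i] + norm[i + 1] <= 0:
            continue
        v1 = (-1.0, norm[i - 1] - norm[i])
        v2 = (1.0, norm[i + 1] - norm[i])
        dot = v1[0] * v2[0] + v1[1] * v2[1]
        cos = dot / (math.hypot(*v1) * math.hypot(*v2))
        bend = math.pi - math.acos(max(-1.0, min(1.0, cos)))
        if bend > best_bend + 1e-12:
            best_bend, best = bend, i + 1
    return best


class TestChooseClusterCount:
    def test_sharpest_bend_at_three(self):
        assert pa.choose_cluster_count([100, 60, 40, 38, 37, 36]) == 3

    def test_linear_curve_falls_back_to_two(self):
        assert pa.choose_cluster_count([100, 90, 80, 70, 60]) == 2

    def test_piecewise_linear_knee(self):
        bic = [100, 80, 60, 40, 20, 19, 18, 17]
        assert pa.choose_cluster_count(bic) == 5

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pa.choose_cluster_count([10, 5])

    def test_rising_limb_bend_ignored(self):
        # U-shaped curve: the knee must sit at/before the minimum, not at a
        # sharp bend in the overfitting (rising) limb
        bic = [887, 890, 886, 880, 873, 882, 890, 900, 910, 949]
        assert pa.choose_cluster_count(bic) == 5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_angle_oracle(self, seed):
        bic = np.random.default_rng(seed).normal(0, 50, size=12).cumsum()
        assert pa.choose_cluster_count(bic) == knee_oracle(bic)

    def test_never_returns_one(self, rng):
        for _ in range(20):
            bic = rng.normal(size=8)
            assert pa.choose_cluster_count(bic) >= 2


class TestMergeSmallClusters:
    def test_small_cluster_absorbed_by_nearest(self):
        scaled = np.r_[np.zeros((30, 1)), np.full((3, 1), 0.5), np.full((30, 1), 5.0)]
        assignments = np.r_[np.zeros(30, int), np.ones(3, int), np.full(30, 2)]
        merged = _merge_small_clusters(assignments, scaled, min_size=20)
        assert set(np.unique(merged)) == {0, 2}
        # the tiny cluster at 0.5 is nearer the cluster at 0 than at 5
        assert np.all(merged[30:33] == 0)


class TestSnarEstimation:
    @pytest.fixture()
    def snar_run(self, snar_reference_runs):
        return snar_reference_runs[0]

    def test_sum_conservation(self, snar_run):
        _, est = snar_run
        assert est.alpha_total == pytest.approx(est.per_cluster_alpha.sum())

    def test_recovers_subclass_structure(self, snar_run):
        data, est = snar_run
        assert est.cluster_model.chosen_c in (5, 6)
        labels = np.unique(est.cluster_model.assignments)
        assert len(est.per_cluster_alpha) == len(labels)
        # every labeled positive assigned exactly once
        assert est.cluster_model.assignments.shape == (data.n_pos,)

    def test_alpha_total_near_truth(self, snar_run):
        _, est = snar_run
        assert 0.1 <= est.alpha_total <= 0.3

    def test_deterministic_given_seed(self):
        data = pa.make_snar(pa.SyntheticSpec(
            n_pos=400, n_unl=1_000, frac_k=20, n_subclasses=2,
            n_features=12, n_informative=8, seed=3))
        a = pa.estimate_alpha_snar(data, max_c=4, seed=3, folds=3)
        b = pa.estimate_alpha_snar(data, max_c=4, seed=3, folds=3)
        assert a.alpha_total == b.alpha_total
        assert a.cluster_model.chosen_c == b.cluster_model.chosen_c
        assert np.array_equal(a.cluster_model.assignments,
                              b.cluster_model.assignments)

    def test_forced_cluster_count_override(self):
        # n_clusters bypasses the knee selection; sums stay consistent
        data = pa.make_snar(pa.SyntheticSpec(
            n_pos=400, n_unl=1_000, frac_k=20, n_subclasses=2,
            n_features=12, n_informative=8, seed=3))
        forced = pa.estimate_alpha_snar(data, max_c=4, seed=3, folds=3,
                                        n_clusters=4, min_cluster_size=10)
        assert forced.cluster_model.chosen_c == 4
        assert len(forced.per_cluster_alpha) == len(
            np.unique(forced.cluster_model.assignments))
        assert forced.alpha_total == pytest.approx(forced.per_cluster_alpha.sum())

    def test_disjoint_negatives_yield_small_alpha(self):
        # unlabeled set with no hidden positives and negatives well separated
        # from every positive subclass
        data = pa.make_snar(pa.SyntheticSpec(
            n_pos=600, n_unl=1_500, frac_k=0, n_subclasses=3,
            n_features=20, n_informative=12, class_sep=2.0, seed=2))
        est = pa.estimate_alpha_snar(data, max_c=6, seed=2, folds=3)
        assert est.alpha_total <= 0.05
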