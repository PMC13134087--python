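"""Metric oracles: closed forms, symmetry, cross-implementation checks."""

import numpy as np
import pytest

from lispcn.evalmetrics import (auc_ci, auc_rank, classification_metrics,
                                compare_auc, dice, ecdf,
                                feature_distribution_compare, fid,
                                lpips_like, permutation_mean_test, psnr, ssim)
from lispcn.network import PerceptualNet


class TestSsim:
    def test_self_similarity_is_one(self, rng):
        x = rng.uniform(-1, 1, (3, 32, 32))
        assert ssim(x, x) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        x = rng.uniform(-1, 1, (3, 32, 32))
        y = rng.uniform(-1, 1, (3, 32, 32))
        assert ssim(x, y) == pytest.approx(ssim(y, x))

    def test_constant_images_luminance_closed_form(self):
        # [0,1]-scale values 0.2 and 0.8 -> [-1,1] inputs -0.6 and 0.6
        a = np.full((1, 24, 24), -0.6)
        b = np.full((1, 24, 24), 0.6)
        c1 = 0.01 ** 2
        expected = (2 * 0.2 * 0.8 + c1) / (0.2 ** 2 + 0.8 ** 2 + c1)
        assert ssim(a, b) == pytest.approx(expected, rel=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ssim(np.zeros((3, 8, 8)), np.zeros((3, 16, 16)))


class TestPsnr:
    def test_identical_images_infinite(self, rng):
        x = rng.uniform(-1, 1, (3, 8, 8))
        assert psnr(x, x) == np.inf

    def test_closed_form_20db(self):
        # MSE 0.01 on the [0,1] scale -> 20 dB
        a = np.zeros((1, 10, 10))
        b = np.full((1, 10, 10), 0.2)  # [0,1]-scale difference 0.1
        assert psnr(a, b) == pytest.approx(20.0, rel=1e-9)

    def test_closed_form_0db(self):
        a = np.full((1, 10, 10), -1.0)   # 0.0 in unit scale
        b = np.full((1, 10, 10), 1.0)    # 1.0 in unit scale
        assert psnr(a, b) == pytest.approx(0.0, abs=1e-9)


class TestLpips:
    def test_identical_zero_and_symmetry(self, rng):
        net = PerceptualNet(seed=4)
        x = rng.uniform(-1, 1, (3, 32, 32)).astype(np.float32)
        y = rng.uniform(-1, 1, (3, 32, 32)).astype(np.float32)
        assert lpips_like(x, x.copy(), net) == 0.0
        assert lpips_like(x, y, net) == pytest.approx(
            lpips_like(y, x, net), rel=1e-6)

    def test_monotone_in_noise_amplitude(self):
        net = PerceptualNet(seed=4)
        base_rng = np.random.default_rng(0)
        x = base_rng.uniform(-0.5, 0.5, (3, 32, 32)).astype(np.float32)
        means = []
        for sigma in (0.05, 0.1, 0.2):
            vals = []
            for seed in range(3):
                noise = np.random.default_rng(seed).normal(0, sigma, x.shape)
                vals.append(lpips_like(x, (x + noise).astype(np.float32), net))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestFid:
    def test_identical_sets_zero(self, rng):
        feats = rng.normal(0, 1, (200, 4))
        assert fid(feats, feats.copy()) == pytest.approx(0.0, abs=1e-6)

    def test_mean_shift_closed_form(self):
        rng = np.random.default_rng(0)
        mu = np.array([1.5, 1.5, 1.5, 1.5])  # ||mu||^2 = 9
        a = rng.normal(0, 1, (5000, 4))
        b = rng.normal(0, 1, (5000, 4)) + mu
        assert fid(a, b) == pytest.approx(9.0, abs=0.3)

    def test_symmetry(self, rng):
        a = rng.normal(0, 1, (300, 4))
        b = rng.normal(1, 2, (300, 4))
        assert fid(a, b) == pytest.approx(fid(b, a), rel=1e-6)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fid(rng.normal(0, 1, (1, 4)), rng.normal(0, 1, (10, 4)))


class TestAuc:
    def test_perfect_separation(self):
        m = classification_metrics(np.array([0.9, 0.1]), np.array([1, 0]))
        assert m["auc"] == 1.0 and m["accuracy"] == 1.0

    def test_all_ties_give_half(self):
        assert auc_rank(np.full(10, 0.5),
                        np.array([1, 0] * 5)) == pytest.approx(0.5)

    def test_rank_counting_example(self):
        assert auc_rank(np.array([0.8, 0.7, 0.3]),
                        np.array([1, 0, 1])) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_rank(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_rank_statistic_matches_trapezoidal_roc(self, rng):
        """Two-implementation cross-check against sklearn's trapezoidal
        ROC integration on random score sets (including ties)."""
        from sklearn.metrics import roc_auc_score
        for _ in range(100):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            probs = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert auc_rank(probs, labels) == pytest.approx(
                roc_auc_score(labels, probs), abs=1e-12)

    def test_confusion_metrics_hand_example(self):
        # preds at 0.5: (1, 1, 0, 0) vs labels (1, 0, 1, 0)
        # -> TP=1, FP=1, FN=1, TN=1
        probs = np.array([0.9, 0.6, 0.4, 0.2])
        labels = np.array([1, 0, 1, 0])
        m = classification_metrics(probs, labels)
        assert m["accuracy"] == 0.5
        assert m["precision"] == 0.5
        assert m["sensitivity"] == 0.5
        assert m["specificity"] == 0.5
        assert m["f1"] == pytest.approx(0.5)
        assert m["auc"] == pytest.approx(0.75)  # 3 of 4 pairs ordered


class TestAucCi:
    def test_perfect_scores_degenerate_interval(self):
        lo, hi = auc_ci(np.array([0.9, 0.8, 0.2, 0.1]),
                        np.array([1, 1, 0, 0]), n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_seeded_reproducibility(self, rng):
        probs = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        a = auc_ci(probs, labels, n_boot=300, seed=7)
        b = auc_ci(probs, labels, n_boot=300, seed=7)
        assert a == b

    def test_interval_contains_point_estimate(self, rng):
        probs = np.concatenate([rng.normal(0.6, 0.15, 40),
                                rng.normal(0.4, 0.15, 160)])
        labels = np.array([1] * 40 + [0] * 160)
        point = auc_rank(probs, labels)
        lo, hi = auc_ci(probs, labels, n_boot=1000, seed=1)
        assert lo <= point <= hi


class TestCompareAuc:
    def test_identical_models_p_one(self, rng):
        probs = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        assert compare_auc(probs, probs.copy(), labels,
                           n_perm=200, seed=0) == 1.0

    def test_p_in_unit_interval(self, rng):
        a, b = rng.random(40), rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        p = compare_auc(a, b, labels, n_perm=300, seed=0)
        assert 0 < p <= 1

    def test_detects_large_separation(self):
        rng = np.random.default_rng(3)
        n = 200
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        strong = labels + rng.normal(0, 0.35, n)     # AUC ~0.95
        weak = labels + rng.normal(0, 4.0, n)        # AUC ~0.55
        assert compare_auc(strong, weak, labels, n_perm=2000, seed=0) < 0.01

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_auc(rng.random(5), rng.random(6), np.zeros(5, int))


class TestFeatureDistribution:
    def test_sample_vs_itself_p_one(self, rng):
        x = rng.normal(0, 1, 300)
        out = feature_distribution_compare(x, x.copy(), seed=0)
        assert out["p_value"] == 1.0

    def test_ecdf_monotone_zero_to_one(self, rng):
        x = rng.normal(0, 1, 200)
        grid = np.linspace(-4, 4, 101)
        e = ecdf(x, grid)
        assert e[0] == 0.0 and e[-1] == 1.0
        assert (np.diff(e) >= 0).all()

    def test_detects_mean_shift(self):
        rng = np.random.default_rng(1)
        out = feature_distribution_compare(rng.normal(0, 1, 500),
                                           rng.normal(2, 1, 500), seed=0)
        assert out["p_value"] < 0.01

    def test_ks_flag(self, rng):
        out = feature_distribution_compare(rng.normal(0, 1, 100),
                                           rng.normal(0, 1, 100),
                                           seed=0, test="ks")
        assert 0 < out["p_value"] <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            feature_distribution_compare(np.array([]), np.array([1.0]))


class TestDice:
    def test_identical_masks_one(self, rng):
        m = rng.random((16, 16)) > 0.5
        assert dice(m, m.copy()) == 1.0

    def test_disjoint_masks_zero(self):
        a = np.zeros((8, 8), int)
        b = np.zeros((8, 8), int)
        a[:2], b[6:] = 1, 1
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((20, 20), int)
        b = np.zeros((20, 20), int)
        a[:10] = 1          # 200 px... use 100/100/50 structure
        a = np.zeros(400, int)
        b = np.zeros(400, int)
        a[:100] = 1
        b[50:150] = 1
        assert dice(a.reshape(20, 20), b.reshape(20, 20)) == 0.5

    def test_both_empty_convention(self):
        assert dice(np.zeros((4, 4), int), np.zeros((4, 4), int)) == 1.0

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            dice(np.full((4, 4), 2), np.zeros((4, 4), int))


class TestBoundedMetricFuzz:
    def test_ranges_on_random_inputs(self, rng):
        for _ in range(25):
            x = rng.uniform(-1, 1, (3, 16, 16))
            y = rng.uniform(-1, 1, (3, 16, 16))
            assert -1 <= ssim(x, y) <= 1
            ma = rng.random((16, 16)) > rng.random()
            mb = rng.random((16, 16)) > rng.random()
            assert 0 <= dice(ma, mb) <= 1
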