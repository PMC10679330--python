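"""IS/FID/KID closed forms, classification metrics, paired t-test."""

import numpy as np
import pytest
import scipy.stats

from msgaug import (ConfusionMatrix, IdentityFeatures, RawMomentFeatures,
                    classification_metrics, confusion_from_predictions, fid,
                    inception_score, kid, paired_t_test)


class TestInceptionScore:
    def test_uniform_rows_give_exactly_one(self):
        probs = np.full((100, 9), 1 / 9)
        mean, std = inception_score(probs, n_splits=10)
        assert mean == pytest.approx(1.0, abs=1e-9)
        assert std == pytest.approx(0.0, abs=1e-9)

    def test_balanced_one_hot_two_classes_gives_two(self):
        probs = np.tile(np.eye(2), (50, 1))      # alternating one-hot rows
        mean, _ = inception_score(probs, n_splits=10)
        assert mean == pytest.approx(2.0, abs=1e-6)

    def test_identical_one_hot_gives_one(self):
        probs = np.tile([1.0, 0.0], (60, 1))
        mean, _ = inception_score(probs, n_splits=10)
        assert mean == pytest.approx(1.0, abs=1e-9)

    def test_bounds_hold_for_random_rows(self, rng):
        for k in (2, 5, 9):
            probs = rng.dirichlet(np.ones(k), size=200)
            mean, _ = inception_score(probs, n_splits=10)
            assert 1.0 - 1e-9 <= mean <= k + 1e-9

    def test_unnormalised_rows_rejected(self):
        with pytest.raises(ValueError):
            inception_score(np.full((20, 3), 0.4), n_splits=2)


def _fid_1d_closed_form(x, y):
    return (x.mean() - y.mean()) ** 2 + (x.std(ddof=1) - y.std(ddof=1)) ** 2


class TestFid:
    def test_identical_sets_give_zero(self, rng):
        x = rng.normal(size=(100, 6))
        assert fid(x, x) == pytest.approx(0.0, abs=1e-6)

    def test_univariate_closed_form(self, rng):
        """1-D FID equals (d mean)^2 + (d sd)^2 on 50 random parameter pairs."""
        for _ in range(50):
            mu1, mu2 = rng.normal(scale=3, size=2)
            s1, s2 = rng.uniform(0.2, 3, size=2)
            x = rng.normal(mu1, s1, size=(80, 1))
            y = rng.normal(mu2, s2, size=(80, 1))
            assert fid(x, y) == pytest.approx(
                _fid_1d_closed_form(x.ravel(), y.ravel()), rel=1e-8, abs=1e-10)

    def test_diagonal_case_sums_coordinatewise(self):
        """When both sample covariances are exactly diagonal (full factorial
        sign design), FID equals the sum of univariate closed forms."""
        import itertools
        signs = np.array(list(itertools.product([-1.0, 1.0], repeat=4)))
        xf = signs * [1.0, 2.0, 0.5, 1.5] + [0.0, 1.0, -1.0, 2.0]
        yf = signs * [1.2, 1.0, 1.0, 0.5] + [0.3, 0.0, 0.0, -0.5]
        expected = sum(_fid_1d_closed_form(xf[:, j], yf[:, j]) for j in range(4))
        assert fid(xf, yf) == pytest.approx(expected, rel=1e-8)

    def test_symmetry_and_rotation_invariance(self, rng):
        x = rng.normal(size=(120, 5))
        y = rng.normal(size=(150, 5)) + 0.7
        assert fid(x, y) == pytest.approx(fid(y, x), abs=1e-8)
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        assert fid(x @ q, y @ q) == pytest.approx(fid(x, y), rel=1e-6)

    def test_dimension_mismatch_and_small_n_rejected(self, rng):
        with pytest.raises(ValueError):
            fid(rng.normal(size=(10, 3)), rng.normal(size=(10, 4)))
        with pytest.raises(ValueError):
            fid(rng.normal(size=(1, 3)), rng.normal(size=(10, 3)))


class TestKid:
    def test_hand_case_minus_three_point_five(self):
        # d=1, X = {0,1}, Y = {0,1}: k(0,0)=1, k(0,1)=1, k(1,1)=8
        x = np.array([[0.0], [1.0]])
        assert kid(x, x.copy()) == pytest.approx(-3.5, abs=1e-12)

    def test_unbiased_near_zero_for_same_distribution(self):
        """Mean over 200 same-distribution repetitions at N=100 lies within
        3 standard errors of zero."""
        rng = np.random.default_rng(7)
        vals = [kid(rng.normal(size=(100, 4)), rng.normal(size=(100, 4)))
                for _ in range(200)]
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_strictly_increases_under_growing_shift(self, rng):
        x = rng.normal(size=(200, 3))
        y = rng.normal(size=(200, 3))
        vals = [kid(x, y + c) for c in np.linspace(0.0, 3.0, 7)]
        assert np.all(np.diff(vals) > 0)

    def test_block_mode_agrees_on_identical_blocks(self, rng):
        x = rng.normal(size=(50, 3))
        y = rng.normal(size=(50, 3))
        tiled_x, tiled_y = np.tile(x, (3, 1)), np.tile(y, (3, 1))
        assert kid(tiled_x, tiled_y, block_size=50) == pytest.approx(kid(x, y))

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            kid(rng.normal(size=(1, 3)), rng.normal(size=(10, 3)))


def _brute_force_metrics(counts):
    k = counts.shape[0]
    total = counts.sum()
    out = []
    for c in range(k):
        tp = counts[c, c]
        fp = sum(counts[r, c] for r in range(k) if r != c)
        fn = sum(counts[c, r] for r in range(k) if r != c)
        tn = total - tp - fp - fn
        out.append((tp / (tp + fp) if tp + fp else np.nan,
                    tp / (tp + fn) if tp + fn else np.nan,
                    tn / (tn + fp) if tn + fp else np.nan))
    return out, np.trace(counts) / total


class TestClassificationMetrics:
    def test_hand_case(self):
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), ["a", "b"])
        rep = classification_metrics(cm)
        row = rep.per_class.set_index("class").loc["a"]
        assert row.precision == pytest.approx(8 / 9)
        assert row.recall == pytest.approx(0.8)
        assert row.specificity == pytest.approx(0.9)
        assert rep.overall_accuracy == pytest.approx(0.85)

    def test_perfect_classifier_all_ones(self):
        cm = ConfusionMatrix(np.diag([5, 3, 7]), ["a", "b", "c"])
        rep = classification_metrics(cm)
        assert rep.overall_accuracy == 1.0
        assert (rep.per_class[["precision", "recall", "specificity"]] == 1.0).all().all()

    def test_never_predicted_class_gives_nan_not_error(self):
        cm = ConfusionMatrix(np.array([[0, 5], [0, 5]]), ["a", "b"])
        rep = classification_metrics(cm)
        assert np.isnan(rep.per_class.set_index("class").loc["a", "precision"])

    @pytest.mark.parametrize("k", range(2, 10))
    def test_agrees_with_brute_force_oracle(self, k, rng):
        counts = rng.integers(0, 30, size=(k, k))
        counts[0, 0] += 1  # non-empty
        rep = classification_metrics(
            ConfusionMatrix(counts, [f"c{i}" for i in range(k)]))
        expected, acc = _brute_force_metrics(counts)
        assert rep.overall_accuracy == pytest.approx(acc)
        for c in range(k):
            got = rep.per_class.iloc[c]
            for name, val in zip(("precision", "recall", "specificity"),
                                 expected[c]):
                if np.isnan(val):
                    assert np.isnan(got[name])
                else:
                    assert got[name] == pytest.approx(val)

    def test_confusion_from_predictions_counts(self):
        cm = confusion_from_predictions([0, 0, 1, 2], [0, 1, 1, 2],
                                        ["a", "b", "c"])
        assert np.array_equal(cm.counts, [[1, 1, 0], [0, 1, 0], [0, 0, 1]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.array([[1, -1], [0, 2]]), ["a", "b"])


class TestPairedTTest:
    def test_hand_case(self):
        t, p = paired_t_test([1, 2, 3], [1, 2, 4])
        assert t == pytest.approx(-1.0, abs=1e-12)
        # df = 2 two-sided p for t = -1
        assert p == pytest.approx(2 * scipy.stats.t.sf(1.0, df=2), abs=1e-12)

    def test_constant_difference_gives_nan_marker(self):
        t, p = paired_t_test([1, 2, 3, 4, 5], [0, 1, 2, 3, 4])
        assert np.isnan(t) and np.isnan(p)

    def test_identical_samples_give_nan_marker(self):
        t, p = paired_t_test([3.0, 3.5], [3.0, 3.5])
        assert np.isnan(t) and np.isnan(p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1, 2], [1, 2, 3])

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(100):
            n = rng.integers(2, 30)
            a = rng.normal(size=n)
            b = a + rng.normal(size=n)
            t, p = paired_t_test(a, b)
            ref = scipy.stats.ttest_rel(a, b)
            assert t == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestFeatureExtractors:
    def test_identity_flattens(self, tiny_dataset):
        feats = IdentityFeatures()(tiny_dataset)
        assert feats.shape == (len(tiny_dataset), 16 * 16 * 3)

    def test_raw_moments_shape_and_sensitivity(self, tiny_dataset):
        ext = RawMomentFeatures()
        feats = ext(tiny_dataset)
        assert feats.shape == (len(tiny_dataset), 12)
        assert np.all(np.isfinite(feats))
        # different texture classes separate in feature space
        m0 = feats[tiny_dataset.labels == 0].mean(axis=0)
        m2 = feats[tiny_dataset.labels == 2].mean(axis=0)
        assert np.linalg.norm(m0 - m2) > 0.1
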