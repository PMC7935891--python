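"""Metric suite vs independent brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from dermseg import (ConfusionCounts, classification_report, hausdorff,
                     pixel_confusion, rates, topn_accuracy,
                     weighted_class_metrics)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def confusion_oracle(pred, truth):
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            if pred[i, j] and truth[i, j]:
                tp += 1
            elif pred[i, j] and not truth[i, j]:
                fp += 1
            elif not pred[i, j] and truth[i, j]:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def hausdorff_oracle(a, b):
    X = np.argwhere(a)
    Y = np.argwhere(b)
    h_xy = max(min(np.hypot(*(x - y)) for y in Y) for x in X)
    h_yx = max(min(np.hypot(*(y - x)) for x in X) for y in Y)
    return max(h_xy, h_yx)


def auc_mann_whitney(scores, positives):
    """Rank-statistic AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    ranks = rankdata(scores)
    n_pos = positives.sum()
    n_neg = len(positives) - n_pos
    u = ranks[positives].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestPixelConfusion:
    def test_all_white_agreement(self):
        m = np.ones((6, 7), bool)
        c = pixel_confusion(m, m)
        assert (c.tp, c.fp, c.tn, c.fn) == (42, 0, 0, 0)

    def test_all_white_vs_all_black(self):
        c = pixel_confusion(np.ones((4, 4), bool), np.zeros((4, 4), bool))
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 16, 0, 0)

    def test_matches_loop_oracle_on_random_pairs(self, rng):
        for _ in range(20):
            pred = rng.random((32, 32)) > 0.5
            truth = rng.random((32, 32)) > 0.5
            c = pixel_confusion(pred, truth)
            assert (c.tp, c.fp, c.tn, c.fn) == confusion_oracle(pred, truth)
            assert c.total == 32 * 32

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pixel_confusion(np.ones((2, 2), bool), np.ones((3, 3), bool))

    def test_swap_maps_sensitivity_to_precision(self, rng):
        pred = rng.random((16, 16)) > 0.4
        truth = rng.random((16, 16)) > 0.6
        c = pixel_confusion(pred, truth)
        c_sw = pixel_confusion(truth, pred)
        # swapping arguments transposes fp <-> fn
        assert (c_sw.tp, c_sw.fp, c_sw.fn) == (c.tp, c.fn, c.fp)
        precision = c.tp / (c.tp + c.fp)
        assert rates(c_sw).sensitivity == pytest.approx(precision)


class TestRates:
    def test_direct_formulas(self):
        r = rates(ConfusionCounts(tp=9, fp=0, tn=0, fn=1))
        assert r.sensitivity == pytest.approx(0.9)
        r2 = rates(ConfusionCounts(tp=1, fp=1, tn=0, fn=1))
        assert r2.dice == pytest.approx(0.5)
        assert r2.f1 == pytest.approx(0.5)

    def test_dice_equals_f1_exactly(self, rng):
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 500, 4)
            r = rates(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert r.dice == r.f1

    def test_zero_denominator_sentinel(self):
        r = rates(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert r.sensitivity == 1.0
        assert "sensitivity" in r.vacuous

    def test_bounds(self, rng):
        for _ in range(200):
            tp, fp, tn, fn = rng.integers(0, 100, 4)
            r = rates(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            for v in (r.sensitivity, r.specificity, r.dice, r.f1):
                assert 0.0 <= v <= 1.0


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        m = rng.random((10, 10)) > 0.5
        m[0, 0] = True
        assert hausdorff(m, m) == 0.0

    def test_single_pair_euclidean(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[3, 4] = True
        assert hausdorff(a, b) == pytest.approx(5.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hausdorff(np.zeros((4, 4), bool), np.ones((4, 4), bool))

    def test_matches_brute_force_and_scipy(self, rng):
        for _ in range(15):
            a = rng.random((24, 24)) > 0.8
            b = rng.random((24, 24)) > 0.8
            if not a.any() or not b.any():
                continue
            h = hausdorff(a, b)
            assert h == pytest.approx(hausdorff_oracle(a, b), abs=1e-12)
            X, Y = np.argwhere(a).astype(float), np.argwhere(b).astype(float)
            h_scipy = max(directed_hausdorff(X, Y)[0], directed_hausdorff(Y, X)[0])
            assert h == pytest.approx(h_scipy, abs=1e-12)
            assert hausdorff(b, a) == h  # symmetry


class TestWeightedMetrics:
    def test_equal_counts_is_mean(self):
        assert weighted_class_metrics({0: 0.4, 1: 0.8}, {0: 5, 1: 5}) == pytest.approx(0.6)

    def test_example_weighting(self):
        assert weighted_class_metrics({0: 0.2, 1: 0.8}, {0: 3, 1: 1}) == pytest.approx(0.35)

    def test_zero_count_class_excluded(self):
        assert weighted_class_metrics({0: 0.2, 1: 1.0}, {0: 4, 1: 0}) == pytest.approx(0.2)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            weighted_class_metrics({0: 0.5}, {0: 0})

    def test_matches_summation_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 8))
            metrics = {c: float(rng.random()) for c in range(k)}
            counts = {c: int(rng.integers(1, 50)) for c in range(k)}
            expected = sum(metrics[c] * counts[c] for c in range(k)) / sum(counts.values())
            got = weighted_class_metrics(metrics, counts)
            assert got == pytest.approx(expected, abs=1e-12)
            assert min(metrics.values()) <= got <= max(metrics.values())


class TestTopN:
    def test_full_n_is_one(self, rng):
        P = rng.random((10, 4))
        P /= P.sum(1, keepdims=True)
        labels = rng.integers(0, 4, 10)
        assert topn_accuracy(P, labels, (4,))[4] == 1.0

    def test_rank_two_sample(self):
        P = np.array([[0.3, 0.5, 0.2]])
        out = topn_accuracy(P, [0], (1, 2))
        assert out[1] == 0.0 and out[2] == 1.0

    def test_ties_break_to_lowest_index(self):
        P = np.array([[0.4, 0.4, 0.2]])
        assert topn_accuracy(P, [0], (1,))[1] == 1.0
        assert topn_accuracy(P, [1], (1,))[1] == 0.0

    def test_monotone_and_matches_sort_oracle(self, rng):
        P = rng.random((50, 6))
        labels = rng.integers(0, 6, 50)
        ns = tuple(range(1, 7))
        out = topn_accuracy(P, labels, ns)
        prev = 0.0
        for n in ns:
            order = np.argsort(-P, axis=1, kind="stable")
            expected = np.mean([labels[i] in order[i, :n] for i in range(50)])
            assert out[n] == pytest.approx(expected)
            assert out[n] >= prev
            prev = out[n]

    def test_n_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            topn_accuracy(np.ones((2, 3)) / 3, [0, 1], (4,))


class TestClassificationReport:
    def test_perfect_predictions(self):
        labels = np.array([0, 1, 2, 0, 1, 2])
        P = np.eye(3)[labels] * 0.98 + 0.01
        rep = classification_report(P, labels, 3)
        for m in ("sensitivity", "specificity", "f1", "auc"):
            assert rep.weighted[m] == pytest.approx(1.0)
        assert rep.accuracy == 1.0

    def test_absent_class_warned_and_excluded(self):
        labels = np.array([0, 0, 1, 1])
        P = np.full((4, 3), 1 / 3)
        rep = classification_report(P, labels, 3)
        assert 2 not in rep.per_class
        assert any("class 2" in w for w in rep.warnings)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            classification_report(np.ones((3, 2)) / 2, np.array([5, 5, 5]), 2)

    def test_auc_matches_rank_oracle_and_sklearn(self, rng):
        P = rng.random((200, 4))
        P /= P.sum(1, keepdims=True)
        labels = rng.integers(0, 4, 200)
        rep = classification_report(P, labels, 4)
        for c in range(4):
            pos = labels == c
            expected = auc_mann_whitney(P[:, c], pos)
            assert rep.per_class[c]["auc"] == pytest.approx(expected, abs=1e-9)
            assert rep.per_class[c]["auc"] == pytest.approx(
                roc_auc_score(pos, P[:, c]), abs=1e-9)

    def test_weighted_values_within_per_class_range(self, rng):
        P = rng.random((100, 3))
        P /= P.sum(1, keepdims=True)
        labels = rng.integers(0, 3, 100)
        rep = classification_report(P, labels, 3)
        for m in ("sensitivity", "specificity", "f1", "auc"):
            vals = [rep.per_class[c][m] for c in rep.per_class]
            assert min(vals) - 1e-12 <= rep.weighted[m] <= max(vals) + 1e-12
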