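"""Confusion matrices and metric formulas against independent oracles."""

import numpy as np
import pytest

import sporeseg as ss
from sporeseg.evaluate import PerClassCounts, metrics_report, per_class_counts

try:
    from sklearn import metrics as skm

    HAVE_SKLEARN = True
except ImportError:  # pragma: no cover
    HAVE_SKLEARN = False


def _random_labels(rng, n):
    return rng.integers(1, 9, n), rng.integers(1, 9, n)


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self, rng):
        t = rng.integers(1, 9, 50)
        cm = ss.confusion_matrix(t, t)
        off = cm.counts - np.diag(np.diag(cm.counts))
        assert off.sum() == 0

    def test_total_conserved(self, rng):
        t, p = _random_labels(rng, 123)
        assert ss.confusion_matrix(t, p).total == 123

    def test_small_example_counts(self):
        cm = ss.confusion_matrix([2, 2, 3], [2, 3, 3])
        assert cm.counts[1, 1] == 1  # true 2 predicted 2
        assert cm.counts[1, 2] == 1  # true 2 predicted 3
        assert cm.counts[2, 2] == 1  # true 3 predicted 3
        assert cm.total == 3

    def test_rejects_out_of_range_and_mismatch(self):
        with pytest.raises(ValueError):
            ss.confusion_matrix([0, 1], [1, 1])
        with pytest.raises(ValueError):
            ss.confusion_matrix([1, 2], [1])


class TestPerClassCounts:
    def test_three_class_worked_example(self):
        # 20-sample toy matrix embedded in the 8x8 frame
        counts = np.zeros((8, 8), dtype=int)
        counts[:3, :3] = [[5, 1, 0], [2, 7, 1], [0, 0, 4]]
        c = per_class_counts(ss.ConfusionMatrix(counts=counts), 2)
        assert (c.tp, c.fp, c.fn, c.tn) == (7, 1, 3, 9)

    def test_partition_sums_to_total(self, rng):
        t, p = _random_labels(rng, 200)
        cm = ss.confusion_matrix(t, p)
        for cls in range(1, 9):
            assert per_class_counts(cm, cls).total == cm.total

    def test_diagonal_matrix_has_no_errors(self):
        cm = ss.ConfusionMatrix(counts=np.diag(np.arange(1, 9)))
        for cls in range(1, 9):
            c = per_class_counts(cm, cls)
            assert c.fp == 0 and c.fn == 0


class TestMetricFormulas:
    def test_worked_example(self):
        counts = PerClassCounts(tp=8, fp=2, fn=2, tn=0)
        assert ss.precision(counts) == pytest.approx(0.8)
        assert ss.sensitivity(counts) == pytest.approx(0.8)
        assert ss.f1(counts) == pytest.approx(0.8)

    def test_zero_denominators_give_zero(self):
        counts = PerClassCounts(tp=0, fp=0, fn=0, tn=10)
        assert ss.precision(counts) == 0.0
        assert ss.sensitivity(counts) == 0.0
        assert ss.f1(counts) == 0.0

    def test_oracle_recount_on_500_random_matrices(self, rng):
        """All five formulas agree with a naive per-sample recount."""
        for _ in range(500):
            n = int(rng.integers(8, 60))
            t, p = _random_labels(rng, n)
            cm = ss.confusion_matrix(t, p)
            assert ss.accuracy(cm) == pytest.approx(float((t == p).mean()))
            cls = int(rng.integers(1, 9))
            tp = int(((t == cls) & (p == cls)).sum())
            fp = int(((t != cls) & (p == cls)).sum())
            fn = int(((t == cls) & (p != cls)).sum())
            tn = int(((t != cls) & (p != cls)).sum())
            c = per_class_counts(cm, cls)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
            assert ss.accuracy(c) == pytest.approx((tp + tn) / n)
            assert ss.precision(c) == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
            assert ss.sensitivity(c) == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
            assert ss.f1(c) == pytest.approx(
                2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
            )

    @pytest.mark.skipif(not HAVE_SKLEARN, reason="sklearn unavailable")
    def test_cross_check_against_sklearn(self, rng):
        """Independent library route agrees with the formula route."""
        t, p = _random_labels(rng, 400)
        cm = ss.confusion_matrix(t, p)
        rep = metrics_report(cm)
        labels = list(range(1, 9))
        sk_prec = skm.precision_score(t, p, labels=labels, average=None, zero_division=0)
        sk_rec = skm.recall_score(t, p, labels=labels, average=None, zero_division=0)
        sk_f1 = skm.f1_score(t, p, labels=labels, average=None, zero_division=0)
        assert np.allclose(rep.per_class["precision"].to_numpy(), sk_prec)
        assert np.allclose(rep.per_class["sensitivity"].to_numpy(), sk_rec)
        assert np.allclose(rep.per_class["f1"].to_numpy(), sk_f1)
        assert rep.overall_accuracy == pytest.approx(skm.accuracy_score(t, p))


class TestReportInvariants:
    def test_supports_are_row_sums(self, rng):
        t, p = _random_labels(rng, 300)
        rep = metrics_report(ss.confusion_matrix(t, p))
        assert rep.total_support == 300
        assert np.array_equal(
            rep.per_class["support"].to_numpy(), np.bincount(t, minlength=9)[1:]
        )

    def test_perfect_report(self, rng):
        t = rng.integers(1, 9, 100)
        rep = metrics_report(ss.confusion_matrix(t, t))
        assert rep.overall_accuracy == 1.0


class TestPerImageAccuracy:
    def test_identical_maps(self):
        m = np.full((4, 4), 3, dtype=np.uint8)
        acc = ss.per_image_accuracy([m, m], [m, m])
        assert np.array_equal(acc, [1.0, 1.0])
        assert ss.mean_accuracy(acc) == 1.0

    def test_half_correct(self):
        truth = np.full((2, 2), 3, dtype=np.uint8)
        pred = truth.copy()
        pred[0] = 4
        assert ss.per_image_accuracy([pred], [truth])[0] == 0.5

    def test_mean_is_arithmetic(self):
        assert ss.mean_accuracy([1.0, 0.5, 0.0]) == pytest.approx(0.5)

    def test_unscored_image_excluded_with_warning(self):
        truth = np.zeros((2, 2), dtype=np.uint8)
        pred = np.full((2, 2), 3, dtype=np.uint8)
        with pytest.warns(UserWarning):
            acc = ss.per_image_accuracy([pred], [truth])
        assert acc.size == 0

    def test_pooled_equals_weighted_mean_on_shared_grid(self, rng):
        """Pooled accuracy = support-weighted mean of per-image accuracies."""
        truths = [rng.integers(1, 9, (6, 6)).astype(np.uint8) for _ in range(4)]
        preds = [rng.integers(1, 9, (6, 6)).astype(np.uint8) for _ in range(4)]
        per_img = ss.per_image_accuracy(preds, truths)
        pooled = ss.accuracy(
            ss.confusion_matrix(
                np.concatenate([t.ravel() for t in truths]),
                np.concatenate([p.ravel() for p in preds]),
            )
        )
        assert pooled == pytest.approx(per_img.mean())  # equal supports
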