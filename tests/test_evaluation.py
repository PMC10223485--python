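"""Per-event metrics against brute-force oracles, ROC behaviour, and the
replicate report's self-consistency."""

import numpy as np
import pytest

from falldet.evaluation import (
    class_metrics,
    confusion_counts,
    evaluation_report,
    roc_auc,
    roc_points,
)
from falldet.labels import ClassLabel


def _brute_force_metrics(pred, truth, c):
    """Independent one-vs-rest metric computation by direct enumeration."""
    tp = sum(1 for p, t in zip(pred, truth) if t == c and p == c)
    fn = sum(1 for p, t in zip(pred, truth) if t == c and p != c)
    fp = sum(1 for p, t in zip(pred, truth) if t != c and p == c)
    tn = sum(1 for p, t in zip(pred, truth) if t != c and p != c)
    div = lambda a, b: a / b if b else float("nan")
    return (
        div(tp + tn, tp + tn + fp + fn),
        div(tp, tp + fn),
        div(tn, tn + fp),
    )


class TestConfusionCounts:
    def test_perfect_prediction_has_no_errors(self):
        y = np.array([0, 1, 2, 2, 1, 0])
        c = confusion_counts(y, y)
        assert (c.fp == 0).all() and (c.fn == 0).all()
        assert c.tp.sum() == len(y)

    def test_hand_enumerated_four_item_example(self):
        truth = [2, 2, 1, 0]   # F, F, P, N
        pred = [2, 1, 1, 0]    # F, P, P, N
        c = confusion_counts(pred, truth)
        f = int(ClassLabel.FALL)
        assert (c.tp[f], c.fn[f], c.fp[f], c.tn[f]) == (1, 1, 0, 2)

    def test_counts_partition_the_total(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 3, 50)
        truth = rng.integers(0, 3, 50)
        c = confusion_counts(pred, truth)
        np.testing.assert_array_equal(c.tp + c.fp + c.tn + c.fn, 50)
        assert c.tp.sum() == (pred == truth).sum()

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_counts([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_counts([0, 1], [0, 1, 2])


class TestClassMetrics:
    def test_direct_substitution_example(self):
        # class 0: TP=8, FN=2, FP=1, TN=89 over 100 evaluated blocks
        pred = [0] * 8 + [1] * 2 + [0, 1] + [2] * 88
        truth = [0] * 10 + [1] * 2 + [2] * 88
        m = class_metrics(confusion_counts(pred, truth))
        c = 0
        assert m.sensitivity[c] == pytest.approx(0.80)
        assert m.specificity[c] == pytest.approx(89 / 90)
        assert m.accuracy[c] == pytest.approx(0.97)

    def test_all_correct_gives_ones(self):
        y = np.array([0, 1, 2] * 5)
        m = class_metrics(confusion_counts(y, y))
        np.testing.assert_allclose(m.accuracy, 1.0)
        np.testing.assert_allclose(m.sensitivity, 1.0)
        np.testing.assert_allclose(m.specificity, 1.0)

    def test_absent_class_sensitivity_reported_missing(self):
        m = class_metrics(confusion_counts([0, 0, 1], [0, 0, 1]))
        assert np.isnan(m.sensitivity[int(ClassLabel.FALL)])

    def test_matches_brute_force_on_random_vectors(self, rng):
        """1000 random prediction/truth pairs agree exactly with an
        independently coded enumeration of the one-vs-rest counts."""
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            pred = rng.integers(0, 3, n)
            truth = rng.integers(0, 3, n)
            m = class_metrics(confusion_counts(pred, truth))
            for c in range(3):
                acc, sens, spec = _brute_force_metrics(pred, truth, c)
                for got, want in ((m.accuracy[c], acc),
                                  (m.sensitivity[c], sens),
                                  (m.specificity[c], spec)):
                    if np.isnan(want):
                        assert np.isnan(got)
                    else:
                        assert got == want

    def test_accuracy_invariant_to_other_class_relabeling(self, rng):
        pred = rng.integers(0, 3, 200)
        truth = rng.integers(0, 3, 200)
        m1 = class_metrics(confusion_counts(pred, truth))
        swap = {0: 0, 1: 2, 2: 1}
        pred2 = np.array([swap[p] if p != 0 else 0 for p in pred])
        truth2 = np.array([swap[t] if t != 0 else 0 for t in truth])
        m2 = class_metrics(confusion_counts(pred2, truth2))
        assert m1.accuracy[0] == m2.accuracy[0]


class TestROC:
    def test_perfect_separation_passes_through_corner(self):
        truth = np.array([0, 0, 2, 2])
        scores = np.zeros((4, 3))
        scores[:, 2] = [0.1, 0.2, 0.8, 0.9]
        pts = roc_points(scores, truth, ClassLabel.FALL)
        assert any((p == (0.0, 1.0)).all() for p in pts)
        assert roc_auc(pts) == pytest.approx(1.0)

    def test_constant_scores_give_chance_diagonal(self):
        truth = np.array([0, 2, 0, 2])
        scores = np.full((4, 3), 0.5)
        pts = roc_points(scores, truth, ClassLabel.FALL)
        assert roc_auc(pts) == pytest.approx(0.5)

    def test_monotone_sweep(self, rng):
        truth = rng.integers(0, 3, 60)
        scores = rng.uniform(size=(60, 3))
        pts = roc_points(scores, truth, 1)
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= -1e-12).all()

    def test_auc_equals_pairwise_ordering_fraction(self, rng):
        """Trapezoidal AUC equals the probability a random positive out-scores
        a random negative (ties count half) — checked by enumeration."""
        for _ in range(20):
            n = int(rng.integers(6, 25))
            truth = rng.integers(0, 2, n) * 2          # classes {0, 2}
            if len(set(truth)) < 2:
                continue
            scores = np.zeros((n, 3))
            scores[:, 2] = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            pts = roc_points(scores, truth, 2)
            pos = scores[truth == 2, 2]
            neg = scores[truth == 0, 2]
            pairs = [
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p in pos for q in neg
            ]
            assert roc_auc(pts) == pytest.approx(np.mean(pairs), abs=1e-9)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            roc_points(np.ones((3, 3)) / 2, np.zeros(3, dtype=int), 0)


class _StubModel:
    """Deterministic stand-in classifier for report plumbing tests."""

    def __init__(self, scores):
        self._scores = np.asarray(scores)

    def scores(self, X):
        return self._scores[: len(X)]


class TestEvaluationReport:
    def _test_ds(self):
        from falldet.io_formats import BlockDataset
        n = 9
        y = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2], dtype=np.int8)
        return BlockDataset(
            X=np.zeros((n, 4, 6)), y=y,
            subjects=np.asarray(["SA01"] * n, dtype=object),
            groups=np.asarray(["young"] * n, dtype=object),
            trial_ids=np.asarray(["T"] * n, dtype=object),
            starts=np.zeros(n, dtype=np.int64),
        )

    def _perfect_scores(self, y):
        s = np.full((len(y), 3), 0.1)
        s[np.arange(len(y)), y] = 0.9
        return s

    def test_single_run_has_no_sd_column(self):
        ds = self._test_ds()
        report = evaluation_report(_StubModel(self._perfect_scores(ds.y)), ds)
        assert "sensitivity" in report.metrics.columns
        assert not any("sd" in c for c in report.metrics.columns)

    def test_identical_replicates_have_zero_sd(self):
        ds = self._test_ds()
        models = [_StubModel(self._perfect_scores(ds.y))] * 3
        report = evaluation_report(models, ds)
        sd_cols = [c for c in report.metrics.columns if c.endswith("_sd")]
        assert sd_cols
        np.testing.assert_allclose(report.metrics[sd_cols].to_numpy(), 0.0)

    def test_metrics_recomputable_from_emitted_confusion(self):
        ds = self._test_ds()
        scores = self._perfect_scores(ds.y)
        scores[3] = [0.9, 0.1, 0.1]       # one PRE_FALL misread as NON_FALL
        report = evaluation_report(_StubModel(scores), ds)
        m = report.confusion.to_numpy()
        for c in range(3):
            tp = m[c, c]
            fn = m[c].sum() - tp
            fp = m[:, c].sum() - tp
            tn = m.sum() - tp - fn - fp
            acc = (tp + tn) / m.sum()
            assert report.metrics["accuracy"].iloc[c] == pytest.approx(acc)

    def test_report_files_written(self, tmp_path):
        ds = self._test_ds()
        report = evaluation_report(_StubModel(self._perfect_scores(ds.y)), ds)
        report.write(tmp_path)
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "confusion_matrix.csv").exists()
        assert (tmp_path / "roc_fall.csv").exists()
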