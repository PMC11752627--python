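import math

import numpy as np
import pytest
import sklearn.metrics

from afwave.errors import InputError, ParameterError
from afwave.evaluation import (
    BinaryCounts,
    class_metrics,
    confusion_matrix,
    macro_average,
    one_vs_rest_counts,
    pr_points_and_auc,
    roc_points_and_auc,
    evaluate,
)


def metrics_oracle(tp, fn, tn, fp):
    """Direct evaluation of the six formulas; zero denominators -> 0."""

    def div(a, b):
        return a / b if b else 0.0

    total = tp + fn + tn + fp
    acc = (tp + tn) / total
    se = div(tp, tp + fn)
    sp = div(tn, tn + fp)
    pre = div(tp, tp + fp)
    f1 = div(2 * se * pre, se + pre)
    d = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = div(float(tp) * tn - float(fp) * fn, d)
    return acc, se, sp, pre, f1, mcc


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion_matrix(list("NAO~"), list("NAO~"), list("NAO~"))
        assert np.array_equal(cm.counts, np.eye(4, dtype=int))

    def test_hand_counted_toy(self):
        cm = confusion_matrix(["A", "A", "N"], ["A", "N", "N"], ["A", "N"])
        assert cm.counts.tolist() == [[1, 1], [0, 1]]

    def test_total_equals_sequence_length(self):
        rng = np.random.default_rng(0)
        true = rng.choice(list("NAO~"), 57).tolist()
        pred = rng.choice(list("NAO~"), 57).tolist()
        assert confusion_matrix(true, pred, list("NAO~")).total == 57

    def test_unknown_label_rejected(self):
        with pytest.raises(InputError):
            confusion_matrix(["Z"], ["N"], ["N", "A"])


class TestOneVsRest:
    def test_diagonal_matrix_has_no_errors(self):
        cm = confusion_matrix(list("NA"), list("NA"), ["N", "A"])
        for i in range(2):
            c = one_vs_rest_counts(cm, i)
            assert c.fn == 0 and c.fp == 0

    def test_hand_counted_toy(self):
        cm = confusion_matrix(["A", "A", "N"], ["A", "N", "N"], ["A", "N"])
        c = one_vs_rest_counts(cm, 0)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 0, 1)

    def test_counts_conserve_total(self):
        rng = np.random.default_rng(1)
        true = rng.choice(list("NAO~"), 200).tolist()
        pred = rng.choice(list("NAO~"), 200).tolist()
        cm = confusion_matrix(true, pred, list("NAO~"))
        for i in range(4):
            assert one_vs_rest_counts(cm, i).total == 200

    def test_index_out_of_range(self):
        cm = confusion_matrix(["N"], ["N"], ["N", "A"])
        with pytest.raises(ParameterError):
            one_vs_rest_counts(cm, 2)


class TestClassMetrics:
    def test_perfect_classifier(self):
        m = class_metrics(BinaryCounts(tp=10, fn=0, tn=90, fp=0))
        assert m.as_dict() == {"acc": 1.0, "se": 1.0, "sp": 1.0, "pre": 1.0, "f1": 1.0, "mcc": 1.0}

    def test_worked_example(self):
        m = class_metrics(BinaryCounts(tp=45, fn=5, tn=90, fp=10))
        assert m.se == pytest.approx(0.9000, abs=5e-4)
        assert m.sp == pytest.approx(0.9000, abs=5e-4)
        assert m.pre == pytest.approx(0.8182, abs=5e-4)
        assert m.f1 == pytest.approx(0.8571, abs=5e-4)
        assert m.acc == pytest.approx(0.9000, abs=5e-4)
        assert m.mcc == pytest.approx(0.7826, abs=5e-4)

    def test_degenerate_denominators_flagged(self):
        m = class_metrics(BinaryCounts(tp=0, fn=5, tn=95, fp=0))
        assert m.se == 0.0 and m.pre == 0.0 and m.mcc == 0.0
        assert {"pre", "mcc", "f1"} <= m.degenerate

    def test_all_zero_counts_rejected(self):
        with pytest.raises(InputError):
            class_metrics(BinaryCounts(0, 0, 0, 0))

    def test_agrees_with_formula_oracle_on_random_tables(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            tp, fn, tn, fp = rng.integers(0, 40, 4)
            if tp + fn + tn + fp == 0:
                continue
            m = class_metrics(BinaryCounts(int(tp), int(fn), int(tn), int(fp)))
            expected = metrics_oracle(int(tp), int(fn), int(tn), int(fp))
            for got, want in zip((m.acc, m.se, m.sp, m.pre, m.f1, m.mcc), expected):
                assert got == pytest.approx(want, abs=1e-12)

    def test_mcc_range_and_equality_condition(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            tp, fn, tn, fp = (int(v) for v in rng.integers(0, 20, 4))
            if tp + fn + tn + fp == 0:
                continue
            m = class_metrics(BinaryCounts(tp, fn, tn, fp))
            assert -1.0 <= m.mcc <= 1.0
            if m.mcc == 1.0:
                assert fn == 0 and fp == 0

    def test_cross_check_against_sklearn(self):
        rng = np.random.default_rng(21)
        true = rng.integers(0, 2, 300)
        pred = rng.integers(0, 2, 300)
        cm = confusion_matrix(true.tolist(), pred.tolist(), [1, 0])
        m = class_metrics(one_vs_rest_counts(cm, 0))
        assert m.pre == pytest.approx(sklearn.metrics.precision_score(true, pred))
        assert m.se == pytest.approx(sklearn.metrics.recall_score(true, pred))
        assert m.f1 == pytest.approx(sklearn.metrics.f1_score(true, pred))
        assert m.mcc == pytest.approx(sklearn.metrics.matthews_corrcoef(true, pred))


class TestMacroAverage:
    def test_identical_records_average_to_themselves(self):
        m = class_metrics(BinaryCounts(45, 5, 90, 10))
        avg = macro_average([m, m, m])
        assert avg.as_dict() == m.as_dict()

    def test_two_class_f1_mean(self):
        a = class_metrics(BinaryCounts(8, 2, 10, 2))
        b = class_metrics(BinaryCounts(10, 0, 12, 0))
        avg = macro_average([a, b])
        assert avg.f1 == pytest.approx((a.f1 + b.f1) / 2)

    def test_mean_of_k_records(self):
        rng = np.random.default_rng(13)
        records = [
            class_metrics(BinaryCounts(*(int(v) + 1 for v in rng.integers(0, 30, 4))))
            for _ in range(6)
        ]
        avg = macro_average(records)
        for name in ("acc", "se", "sp", "pre", "f1", "mcc"):
            assert getattr(avg, name) == pytest.approx(
                sum(getattr(r, name) for r in records) / 6
            )


class TestRoc:
    def test_perfect_separation(self):
        curve = roc_points_and_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(31)
        scores = rng.uniform(size=4000)
        truth = rng.integers(0, 2, 4000)
        assert roc_points_and_auc(scores, truth).auc == pytest.approx(0.5, abs=0.05)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(size=50)
        y = rng.integers(0, 2, 50)
        a = roc_points_and_auc(s, y).auc
        b = roc_points_and_auc(1.0 - s, y).auc
        assert a + b == pytest.approx(1.0)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(17)
        s = rng.uniform(0.01, 0.99, 80)
        y = rng.integers(0, 2, 80)
        a = roc_points_and_auc(s, y).auc
        b = roc_points_and_auc(s**3, y).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(23)
        s = rng.uniform(size=200)
        y = rng.integers(0, 2, 200)
        assert roc_points_and_auc(s, y).auc == pytest.approx(
            sklearn.metrics.roc_auc_score(y, s), abs=1e-12
        )

    def test_single_class_truth_rejected(self):
        with pytest.raises(InputError):
            roc_points_and_auc([0.1, 0.9], [1, 1])


class TestPr:
    def test_perfect_separation(self):
        curve = pr_points_and_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)
        assert curve.recall_at_precision(0.9) == pytest.approx(1.0)

    def test_all_positive_predictions_precision_is_prevalence(self):
        y = np.array([1, 0, 0, 0, 1])
        s = np.full(5, 0.7)
        curve = pr_points_and_auc(s, y)
        # single threshold: everything predicted positive
        assert curve.precision[-1] == pytest.approx(0.4)
        assert curve.recall[-1] == pytest.approx(1.0)

    def test_matches_exhaustive_threshold_enumeration(self):
        s = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.1])
        y = np.array([1, 0, 1, 1, 0, 0])
        curve = pr_points_and_auc(s, y)
        for thr in np.unique(s):
            pred = s >= thr
            prec = (pred & (y == 1)).sum() / pred.sum()
            rec = (pred & (y == 1)).sum() / 3
            i = np.argmin(np.abs(curve.thresholds - thr))
            assert curve.precision[i + 1] == pytest.approx(prec)
            assert curve.recall[i + 1] == pytest.approx(rec)

    def test_trapezoid_area_matches_sklearn_auc(self):
        rng = np.random.default_rng(41)
        s = rng.uniform(size=300)
        y = rng.integers(0, 2, 300)
        prec, rec, _ = sklearn.metrics.precision_recall_curve(y, s)
        expected = sklearn.metrics.auc(rec[::-1], prec[::-1])
        assert pr_points_and_auc(s, y).auc == pytest.approx(expected, abs=0.02)

    def test_no_positives_rejected(self):
        with pytest.raises(InputError):
            pr_points_and_auc([0.2, 0.4], [0, 0])


class TestEvaluate:
    def test_full_report_structure(self):
        rng = np.random.default_rng(3)
        classes = list("NAO~")
        true = rng.choice(classes, 120).tolist()
        scores = rng.dirichlet(np.ones(4), size=120)
        pred = [classes[i] for i in scores.argmax(axis=1)]
        report = evaluate(true, pred, classes, scores=scores)
        assert set(report.per_class) == set(classes)
        assert set(report.auc_roc) == set(classes)
        d = report.to_dict()
        assert d["macro"]["f1"] == pytest.approx(
            np.mean([report.per_class[c].f1 for c in classes])
        )
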