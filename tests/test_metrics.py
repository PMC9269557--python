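"""Evaluation metrics: published worked examples, oracles, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import octlite as ol
from octlite.metrics import (
    BinaryCounts,
    class_metrics,
    confusion,
    evaluate,
    f_beta_score,
    g_measure,
    macro,
    one_vs_rest,
    overall_accuracy,
)

CLASSES = ol.CLASS_ORDER

count_grids = st.lists(
    st.integers(min_value=0, max_value=50), min_size=16, max_size=16
).map(lambda v: np.array(v).reshape(4, 4))


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = [c for c in CLASSES for _ in range(10)]
        cm = confusion(y, y)
        assert np.array_equal(cm.counts, np.eye(4, dtype=int) * 10)

    def test_all_predicted_first_class(self):
        y = [c for c in CLASSES for _ in range(3)]
        cm = confusion(y, ["CNV"] * 12)
        assert cm.counts[:, 0].sum() == 12
        assert cm.counts[:, 1:].sum() == 0

    def test_single_misclassification_trace(self):
        y_true = [CLASSES[i % 4] for i in range(968)]
        y_pred = list(y_true)
        y_pred[0] = "DME"  # true CNV predicted DME
        cm = confusion(y_true, y_pred)
        assert np.trace(cm.counts) == 967
        assert cm.total == 968

    def test_row_and_column_sums(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        cm = confusion(y_true, y_pred)
        assert np.array_equal(
            cm.counts.sum(axis=1), np.bincount(y_true, minlength=4)
        )
        assert np.array_equal(
            cm.counts.sum(axis=0), np.bincount(y_pred, minlength=4)
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            confusion([], [])
        with pytest.raises(ValueError, match="XYZ"):
            confusion(["XYZ"], ["CNV"])

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 4, 500)
        y_pred = rng.integers(0, 4, 500)
        cm = confusion(y_true, y_pred)
        ref = sklearn_metrics.confusion_matrix(y_true, y_pred, labels=range(4))
        assert np.array_equal(cm.counts, ref)


class TestOneVsRest:
    def test_diagonal_matrix_has_no_errors(self):
        cm = confusion([c for c in CLASSES], [c for c in CLASSES])
        for c in CLASSES:
            bc = one_vs_rest(cm, c)
            assert bc.FP == 0 and bc.FN == 0

    def test_single_error_attribution(self):
        cm = confusion(["DME"], ["CNV"])
        assert one_vs_rest(cm, "CNV").FP == 1
        assert one_vs_rest(cm, "DME").FN == 1

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(count_grids)
    def test_counts_partition_total(self, grid):
        from octlite.metrics import ConfusionMatrix

        cm = ConfusionMatrix(counts=grid)
        for c in CLASSES:
            bc = one_vs_rest(cm, c)
            assert bc.TP + bc.FP + bc.FN + bc.TN == cm.total


class TestClassMetrics:
    def test_published_f1_worked_example(self):
        # recall 0.9876, precision 0.9122 -> F1 0.9484 at 4 dp
        assert round(f_beta_score(0.9876, 0.9122), 4) == 0.9484

    def test_published_g_measure_worked_example(self):
        # precision 0.9658, recall 0.9649 -> G 0.9653 at 4 dp
        assert round(g_measure(0.9649, 0.9658), 4) == 0.9653

    def test_f1_equals_general_beta_formula(self):
        """The harmonic-mean F1 formula and the Fβ formula at β=1 agree on
        1000 random (TP, FP, FN) triples."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            tp, fp, fn = rng.integers(1, 100, 3)
            r = tp / (tp + fn)
            p = tp / (tp + fp)
            direct = 2 * r * p / (r + p)
            assert f_beta_score(r, p, beta=1.0) == pytest.approx(direct, rel=1e-12)

    def test_undefined_metrics_flagged_not_zeroed(self):
        bc = BinaryCounts(TP=0, FP=0, FN=5, TN=10)
        m = class_metrics(bc)
        assert not m.defined
        assert math.isnan(m.recall) and math.isnan(m.f_beta)

    def test_matches_sklearn_per_class(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 4, 400)
        y_pred = rng.integers(0, 4, 400)
        cm = confusion(y_true, y_pred)
        p_ref, r_ref, f_ref, _ = sklearn_metrics.precision_recall_fscore_support(
            y_true, y_pred, labels=range(4), zero_division=0
        )
        for i, c in enumerate(CLASSES):
            m = class_metrics(one_vs_rest(cm, c))
            assert m.precision == pytest.approx(p_ref[i])
            assert m.recall == pytest.approx(r_ref[i])
            assert m.f_beta == pytest.approx(f_ref[i])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.integers(min_value=1, max_value=200),
        st.integers(min_value=0, max_value=200),
        st.integers(min_value=0, max_value=200),
    )
    def test_mean_inequality_chain(self, tp, fp, fn):
        """Harmonic <= geometric <= arithmetic: F1 <= G <= (P+R)/2."""
        m = class_metrics(BinaryCounts(TP=tp, FP=fp, FN=fn, TN=0))
        assert m.f_beta <= m.g_measure + 1e-12
        assert m.g_measure <= (m.precision + m.recall) / 2 + 1e-12


class TestAccuracy:
    def test_one_error_in_968(self):
        y_true = [CLASSES[i % 4] for i in range(968)]
        y_pred = list(y_true)
        y_pred[5] = "NORMAL" if y_pred[5] != "NORMAL" else "CNV"
        cm = confusion(y_true, y_pred)
        assert round(overall_accuracy(cm), 4) == 0.9990

    def test_diagonal_is_one(self):
        cm = confusion(list(CLASSES), list(CLASSES))
        assert overall_accuracy(cm) == 1.0

    def test_uniform_random_labels_near_chance(self):
        rng = np.random.default_rng(3)
        n = 100_000
        cm = confusion(rng.integers(0, 4, n), rng.integers(0, 4, n))
        assert overall_accuracy(cm) == pytest.approx(0.25, abs=0.01)


class TestMacro:
    def test_published_macro_recall_five_layer(self):
        # mean is 0.96485: agreement with the printed 0.9649 at 4 dp
        recalls = (0.9256, 0.9917, 0.9793, 0.9628)
        assert sum(recalls) / 4 == pytest.approx(0.9649, abs=5e-5)

    def test_published_macro_recall_three_layer(self):
        recalls = (0.9876, 0.9298, 0.9380, 0.9876)
        assert round(sum(recalls) / 4, 4) == 0.9607

    def test_identical_values_average_to_themselves(self):
        m = class_metrics(BinaryCounts(TP=9, FP=1, FN=1, TN=29))
        mac = macro([m, m, m, m])
        assert mac.recall == pytest.approx(m.recall)
        assert mac.g_measure == pytest.approx(m.g_measure)

    def test_any_undefined_makes_macro_undefined(self):
        good = class_metrics(BinaryCounts(TP=9, FP=1, FN=1, TN=29))
        bad = class_metrics(BinaryCounts(TP=0, FP=0, FN=3, TN=30))
        mac = macro([good, good, good, bad])
        assert not mac.defined


def test_evaluate_full_report_consistency():
    rng = np.random.default_rng(4)
    y_true = rng.integers(0, 4, 300)
    y_pred = np.where(rng.random(300) < 0.8, y_true, rng.integers(0, 4, 300))
    report = evaluate(y_true, y_pred)
    assert report.cm.total == 300
    assert 0 <= report.accuracy <= 1
    per = [report.per_class[c] for c in CLASSES]
    assert report.macro_recall == pytest.approx(sum(m.recall for m in per) / 4)
    frame = report.to_frame()
    assert list(frame["Class"]) == list(CLASSES) + ["macro"]
    pct = report.cm.percentages()
    assert pct.sum() == pytest.approx(1.0)
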