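"""Confusion-matrix metrics under the macro-averaging convention."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amdnet.metrics import (
    ConfusionMatrix,
    EmptyMatrixError,
    accuracy,
    confusion,
    f1_from_macros,
    macro_precision,
    macro_recall,
    percent,
    report,
)
from tests.conftest import NOOR_CONFUSION, PRIVATE_CONFUSION


class TestConfusionConstruction:
    def test_perfect_predictions_are_diagonal(self):
        labels = [0, 1, 2, 0, 1, 2, 1, 0, 2, 1]
        cm = confusion(labels, labels, k=3)
        assert np.trace(cm.counts) == 10
        assert cm.counts.sum() - np.trace(cm.counts) == 0

    def test_reference_matrix_from_listed_outcomes(self):
        # per-class outcomes of the clinical test split: dry 98/1/5,
        # normal 133 all correct, wet 109 correct + 1 as dry
        true = [0] * 104 + [1] * 133 + [2] * 110
        pred = [0] * 98 + [1] * 1 + [2] * 5 + [1] * 133 + [0] * 1 + [2] * 109
        cm = confusion(true, pred, k=3)
        np.testing.assert_array_equal(cm.counts, PRIVATE_CONFUSION)

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=1, max_size=60))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_counts_agree_with_pair_enumeration(self, pairs):
        true = [t for t, _ in pairs]
        pred = [p for _, p in pairs]
        cm = confusion(true, pred, k=4)
        for i in range(4):
            for j in range(4):
                assert cm.counts[i, j] == sum(
                    1 for t, p in pairs if (t, p) == (i, j)
                )

    def test_out_of_range_label_is_named(self):
        with pytest.raises(ValueError, match="5"):
            confusion([0, 5], [0, 0], k=3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0], k=2)


class TestHeadlineMetrics:
    def test_reference_accuracy(self):
        cm = ConfusionMatrix(PRIVATE_CONFUSION)
        assert accuracy(cm) == 340 / 347
        assert percent(accuracy(cm)) == 97.98

    def test_reference_macro_precision_recall_f1(self):
        cm = ConfusionMatrix(PRIVATE_CONFUSION)
        mp, mr = macro_precision(cm), macro_recall(cm)
        assert percent(mp) == 97.95
        assert percent(mr) == 97.77
        assert percent(f1_from_macros(mp, mr)) == 97.86

    def test_all_diagonal_matrix_scores_perfectly(self):
        rep = report(ConfusionMatrix(NOOR_CONFUSION))
        pct = rep.as_percentages()
        assert pct == {"accuracy": 100.0, "precision": 100.0, "recall": 100.0, "f1": 100.0}

    def test_uniform_two_class_matrix(self):
        assert accuracy(ConfusionMatrix(np.ones((2, 2), dtype=int))) == 0.5

    def test_identity_matrix_macros(self):
        cm = ConfusionMatrix(np.eye(4, dtype=int))
        assert macro_precision(cm) == macro_recall(cm) == 1.0

    def test_empty_matrix_raises(self):
        with pytest.raises(EmptyMatrixError):
            accuracy(ConfusionMatrix(np.zeros((3, 3), dtype=int)))


class TestHarmonicF1:
    def test_reference_value(self):
        assert round(f1_from_macros(0.97953, 0.97774), 4) == 0.9786

    @given(st.floats(0.01, 1.0))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_idempotent_on_equal_inputs(self, x):
        assert f1_from_macros(x, x) == pytest.approx(x)

    def test_closed_form(self):
        assert f1_from_macros(0.5, 1.0) == pytest.approx(2 / 3)

    def test_zero_convention(self):
        assert f1_from_macros(0.0, 0.0) == 0.0

    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_between_min_and_arithmetic_mean(self, a, b):
        f1 = f1_from_macros(a, b)
        assert min(a, b) - 1e-12 <= f1 <= (a + b) / 2 + 1e-12


class TestOracleAgreement:
    def test_per_class_metrics_match_bruteforce_on_random_matrices(self):
        """One-vs-rest TP/FP/FN arithmetic on 1,000 random small matrices."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = int(rng.integers(2, 5))
            counts = rng.integers(0, 12, size=(k, k))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = ConfusionMatrix(counts)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = report(cm)
            total = counts.sum()
            for i in range(k):
                tp = counts[i, i]
                fp = counts[:, i].sum() - tp
                fn = counts[i, :].sum() - tp
                pr = tp / (tp + fp) if tp + fp else 0.0
                re = tp / (tp + fn) if tp + fn else 0.0
                assert rep.per_class_precision[i] == pytest.approx(pr)
                assert rep.per_class_recall[i] == pytest.approx(re)
            assert rep.accuracy == pytest.approx(np.trace(counts) / total)

    def test_report_matches_sklearn_macro_averages(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        true = rng.integers(0, 3, 200)
        pred = rng.integers(0, 3, 200)
        cm = confusion(true, pred, k=3)
        rep = report(cm)
        pr, re, _, _ = sklearn_metrics.precision_recall_fscore_support(
            true, pred, average="macro", zero_division=0
        )
        assert rep.macro_precision == pytest.approx(pr)
        assert rep.macro_recall == pytest.approx(re)
        assert rep.accuracy == pytest.approx(sklearn_metrics.accuracy_score(true, pred))

    def test_macro_aggregation_not_mean_of_per_class_f1(self):
        """The two aggregation orders genuinely differ on the reference matrix."""
        rep = report(ConfusionMatrix(PRIVATE_CONFUSION))
        mean_of_f1 = float(np.mean(rep.per_class_f1))
        assert percent(mean_of_f1) == 97.83  # the convention this package rejects
        assert percent(rep.f1) == 97.86


class TestInvariances:
    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_class_permutation_leaves_metrics_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, size=(3, 3))
        counts[0, 0] += 1
        perm = rng.permutation(3)
        a = report(ConfusionMatrix(counts))
        b = report(ConfusionMatrix(counts[np.ix_(perm, perm)]))
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.macro_precision == pytest.approx(b.macro_precision)
        assert a.macro_recall == pytest.approx(b.macro_recall)
        assert a.f1 == pytest.approx(b.f1)


class TestZeroDivisionConventions:
    def test_never_predicted_class_warns_and_zeroes_precision(self):
        counts = np.array([[5, 0, 0], [3, 0, 0], [0, 0, 2]])
        cm = ConfusionMatrix(counts)
        with pytest.warns(UserWarning, match="precision"):
            assert macro_precision(cm) == pytest.approx((5 / 8 + 0 + 1) / 3)

    def test_zero_support_class_warns_and_zeroes_recall(self):
        counts = np.array([[5, 0], [0, 0]])
        cm = ConfusionMatrix(counts)
        with pytest.warns(UserWarning, match="recall"):
            assert macro_recall(cm) == pytest.approx(0.5)


class TestSerialization:
    def test_csv_roundtrip(self, tmp_path):
        cm = ConfusionMatrix(PRIVATE_CONFUSION, class_names=["dry", "normal", "wet"])
        path = tmp_path / "cm.csv"
        cm.to_csv(path)
        back = ConfusionMatrix.from_csv(path)
        np.testing.assert_array_equal(back.counts, cm.counts)
        assert back.class_names == cm.class_names

    def test_report_json(self, tmp_path):
        import json

        rep = report(ConfusionMatrix(PRIVATE_CONFUSION))
        path = tmp_path / "report.json"
        rep.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["accuracy"] == pytest.approx(340 / 347)
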