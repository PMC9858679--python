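import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from genechain.errors import ConfigError, DataError
from genechain.metrics import (
    AlphaScoreConfig,
    EvaluationReport,
    alpha_evaluation_score,
    confusion_counts,
    evaluate_predictions,
    hamming_loss,
    jaccard_row_accuracy,
    label_macro_accuracy,
    per_label_report,
    reports_to_frame,
)
from oracles import oracle_alpha, oracle_hamming, oracle_jaccard, oracle_label_macro

indicator_pairs = st.integers(1, 20).flatmap(
    lambda n: st.tuples(
        arrays(np.int_, (n, 12), elements=st.integers(0, 1)),
        arrays(np.int_, (n, 12), elements=st.integers(0, 1)),
    )
)


class TestHammingLoss:
    def test_identity(self):
        y = np.array([[1, 0, 1], [0, 1, 0]])
        assert hamming_loss(y, y) == 0.0

    def test_complement(self):
        y = np.array([[1, 0, 1], [0, 1, 0]])
        assert hamming_loss(y, 1 - y) == 1.0

    def test_hand_example(self):
        y_true = [[1, 0, 1], [0, 1, 0]]
        y_pred = [[1, 1, 1], [0, 0, 0]]
        assert hamming_loss(y_true, y_pred) == pytest.approx(2 / 6)

    def test_shape_mismatch(self):
        with pytest.raises(DataError):
            hamming_loss(np.zeros((2, 3), int), np.zeros((2, 4), int))

    def test_non_binary_rejected(self):
        with pytest.raises(DataError):
            hamming_loss(np.full((2, 3), 2), np.zeros((2, 3), int))


class TestJaccardRowAccuracy:
    def test_identity(self):
        y = np.array([[1, 0, 1]])
        assert jaccard_row_accuracy(y, y) == 1.0

    def test_hand_example(self):
        assert jaccard_row_accuracy([[1, 0, 1]], [[1, 1, 1]]) == pytest.approx(2 / 3)

    def test_empty_union_scores_one(self):
        assert jaccard_row_accuracy([[0, 0, 0]], [[0, 0, 0]]) == 1.0


class TestLabelMacroAccuracy:
    def test_identity(self):
        y = np.eye(4, dtype=int)
        assert label_macro_accuracy(y, y) == 1.0

    def test_one_fully_wrong_column(self):
        y_true = np.zeros((5, 4), dtype=int)
        y_pred = y_true.copy()
        y_pred[:, 2] = 1
        assert label_macro_accuracy(y_true, y_pred) == pytest.approx(0.75)

    def test_oracle_equivalence_fixed(self):
        rng = np.random.default_rng(0)
        yt, yp = rng.integers(0, 2, (6, 12)), rng.integers(0, 2, (6, 12))
        assert label_macro_accuracy(yt, yp) == pytest.approx(
            oracle_label_macro(yt.tolist(), yp.tolist()), abs=1e-15
        )


class TestAlphaScore:
    def test_perfect(self):
        y = np.array([[1, 0, 1, 0]])
        for alpha in (0.5, 1, 2, 4):
            cfg = AlphaScoreConfig(alpha=alpha)
            assert alpha_evaluation_score(y, y, cfg) == 1.0

    def test_disjoint_sets_zero(self):
        y_true = np.array([[1, 1, 0, 0]])
        y_pred = np.array([[0, 0, 1, 1]])
        assert alpha_evaluation_score(y_true, y_pred) == 0.0

    def test_hand_example_alpha1_and_alpha2(self):
        # true labels {0,1}, predicted {0,2} of L=4: FN=1, FP=1, union=3
        y_true = [[1, 1, 0, 0]]
        y_pred = [[1, 0, 1, 0]]
        assert alpha_evaluation_score(y_true, y_pred) == pytest.approx(1 / 3)
        assert alpha_evaluation_score(
            y_true, y_pred, AlphaScoreConfig(alpha=2)
        ) == pytest.approx(1 / 9)

    def test_reduces_to_jaccard(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            yt, yp = rng.integers(0, 2, (8, 12)), rng.integers(0, 2, (8, 12))
            assert alpha_evaluation_score(yt, yp) == pytest.approx(
                jaccard_row_accuracy(yt, yp), abs=1e-12
            )

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            AlphaScoreConfig(alpha=-1)
        with pytest.raises(ConfigError):
            AlphaScoreConfig(beta=1.5)
        with pytest.raises(ConfigError):
            AlphaScoreConfig(gamma=-0.1)


@settings(max_examples=150, deadline=None)
@given(indicator_pairs)
def test_oracle_equivalence_property(pair):
    yt, yp = pair
    assert hamming_loss(yt, yp) == pytest.approx(oracle_hamming(yt.tolist(), yp.tolist()), abs=1e-12)
    assert jaccard_row_accuracy(yt, yp) == pytest.approx(
        oracle_jaccard(yt.tolist(), yp.tolist()), abs=1e-12
    )
    assert label_macro_accuracy(yt, yp) == pytest.approx(
        oracle_label_macro(yt.tolist(), yp.tolist()), abs=1e-12
    )
    assert alpha_evaluation_score(yt, yp) == pytest.approx(
        oracle_alpha(yt.tolist(), yp.tolist()), abs=1e-12
    )


@settings(max_examples=100, deadline=None)
@given(indicator_pairs)
def test_alpha_monotone_and_bounds(pair):
    yt, yp = pair
    scores = [
        alpha_evaluation_score(yt, yp, AlphaScoreConfig(alpha=a)) for a in (0.5, 1, 2, 4)
    ]
    assert all(0.0 <= s <= 1.0 for s in scores)
    assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))
    # complement relation between the two column-wise metrics
    assert hamming_loss(yt, yp) == pytest.approx(1.0 - label_macro_accuracy(yt, yp), abs=1e-12)


class TestPerLabelReport:
    def test_perfect(self):
        labels = np.array([[0, 3], [1, 5], [2, 7]])
        report = per_label_report(labels, labels)
        # all three disorder classes are present, so label 1 is perfect
        block = report["label_1"]
        assert block["accuracy"] == 1.0
        assert block["recall_macro"] == 1.0
        assert block["precision_macro"] == 1.0
        # only 3 of 9 subclass classes occur; absent classes contribute 0
        block = report["label_2"]
        assert block["accuracy"] == 1.0
        assert block["recall_macro"] == pytest.approx(3 / 9)
        for c in (3, 5, 7):
            assert block["per_class"][c]["tp"] == 1

    def test_hand_confusion(self):
        # class 0: tp=2, fp=1, fn=2 in a 3-class single label
        y_true = np.array([0, 0, 0, 0, 1, 2])
        y_pred = np.array([0, 0, 1, 2, 0, 2])
        counts = confusion_counts(y_true, y_pred, 3)
        assert counts[0].tp == 2 and counts[0].fp == 1 and counts[0].fn == 2
        assert counts[0].precision == pytest.approx(2 / 3)
        assert counts[0].recall == pytest.approx(1 / 2)
        assert counts[0].f1 == pytest.approx(4 / 7)

    def test_absent_class_scores_zero(self, caplog):
        labels = np.zeros((4, 2), dtype=int)  # only class 0 present
        import logging

        with caplog.at_level(logging.WARNING, logger="genechain.metrics"):
            report = per_label_report(labels, labels)
        assert report["label_1"]["precision_macro"] == pytest.approx(1 / 3)
        assert any("absent" in r.message for r in caplog.records)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            per_label_report(np.zeros((3, 2), int), np.zeros((4, 2), int))


class TestEvaluationReport:
    def _report(self):
        rng = np.random.default_rng(2)
        labels = np.column_stack([rng.integers(0, 3, 20), rng.integers(0, 9, 20)])
        pred = np.column_stack([rng.integers(0, 3, 20), rng.integers(0, 9, 20)])
        from genechain.preprocess import labels_to_indicator

        return evaluate_predictions(
            labels_to_indicator(labels),
            labels_to_indicator(pred),
            labels,
            pred,
            arm={"learner": "DTC", "split_fraction": 0.8},
        )

    def test_json_round_trip(self):
        report = self._report()
        again = EvaluationReport.from_json(report.to_json())
        assert again.to_dict() == report.to_dict()

    def test_tidy_row_schema(self):
        frame = reports_to_frame([self._report()])
        assert len(frame) == 1
        expected = {
            "label1_accuracy_pct",
            "label1_precision_pct",
            "label1_recall_pct",
            "label1_f1_pct",
            "label2_accuracy_pct",
            "label2_precision_pct",
            "label2_recall_pct",
            "label2_f1_pct",
            "macro_accuracy_pct",
            "macro_accuracy_example_based_pct",
            "hamming_loss",
            "alpha_evaluation_score_pct",
        }
        assert expected <= set(frame.columns)

    def test_rates_in_unit_interval(self):
        report = self._report()
        assert 0 <= report.hamming_loss <= 1
        assert 0 <= report.alpha_score <= 1
        assert 0 <= report.macro_accuracy_label_based <= 1
        assert 0 <= report.macro_accuracy_example_based <= 1
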