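"""Accuracy views, per-class metrics against scikit-learn, finding diffs."""

import random

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from pulmostage.annotation_model import (
    FindingRole,
    PresenceItem,
    PresenceKind,
    TLabel,
    TStageResult,
    TumorFinding,
)
from pulmostage.evaluation import collapse_stage, diff_findings, evaluate
from pulmostage.synthetic_corpus import GoldRecord

LABELS = ["T1a", "T1b", "T1c", "T2", "T2a", "T2b", "T3", "T4"]


class TestEvaluate:
    def test_perfect_predictions(self):
        gold = {f"r{i}": l for i, l in enumerate(LABELS)}
        report = evaluate(dict(gold), gold)
        assert report.accuracy_substage == 1.0
        assert report.accuracy_stage == 1.0
        matrix = np.array(report.confusion)
        assert matrix.sum() == matrix.trace() == 8

    def test_within_stage_error_counts_only_at_substage_level(self):
        gold = {"a": "T1b", "b": "T1c", "c": "T3", "d": "T4"}
        pred = {"a": "T1c", "b": "T1c", "c": "T3", "d": "T4"}
        report = evaluate(pred, gold)
        assert report.accuracy_substage == 0.75
        assert report.accuracy_stage == 1.0

    def test_hand_computed_eight_case_fixture(self):
        gold = dict(zip("abcdefgh",
                        ["T1a", "T1b", "T1c", "T2a", "T2b", "T3", "T4", "T2"]))
        pred = dict(zip("abcdefgh",
                        ["T1a", "T1c", "T1c", "T2a", "T2b", "T3", "T3", "T2a"]))
        report = evaluate(pred, gold)
        assert report.accuracy_substage == pytest.approx(5 / 8)
        assert report.accuracy_stage == pytest.approx(7 / 8)
        t1c = report.per_class["T1c"]
        assert (t1c.precision, t1c.recall, t1c.support) == (0.5, 1.0, 1)
        assert t1c.f1 == pytest.approx(2 / 3)
        t4 = report.per_class["T4"]
        assert t4.precision is None and t4.recall == 0.0 and t4.f1 is None
        t2 = report.per_class["T2"]
        assert t2.precision is None and t2.recall == 0.0
        t2a = report.per_class["T2a"]
        assert (t2a.precision, t2a.recall) == (0.5, 1.0)
        # confusion row sums equal supports
        matrix = np.array(report.confusion)
        for k, label in enumerate(report.labels):
            assert matrix[k].sum() == report.per_class[label].support

    def test_per_class_metrics_match_sklearn(self):
        rng = random.Random(23)
        for _ in range(20):
            n = 100
            y_true = [rng.choice(LABELS) for _ in range(n)]
            y_pred = [rng.choice(LABELS) for _ in range(n)]
            gold = {str(i): y_true[i] for i in range(n)}
            pred = {str(i): y_pred[i] for i in range(n)}
            report = evaluate(pred, gold)
            p, r, f, s = precision_recall_fscore_support(
                y_true, y_pred, labels=report.labels, zero_division=0)
            for k, label in enumerate(report.labels):
                m = report.per_class[label]
                assert m.support == s[k]
                if m.precision is not None:
                    assert m.precision == pytest.approx(p[k])
                if m.recall is not None:
                    assert m.recall == pytest.approx(r[k])
                if m.f1 is not None:
                    assert m.f1 == pytest.approx(f[k])

    def test_micro_recall_equals_substage_accuracy(self):
        rng = random.Random(29)
        y_true = [rng.choice(LABELS) for _ in range(80)]
        y_pred = [rng.choice(LABELS) for _ in range(80)]
        report = evaluate({str(i): y_pred[i] for i in range(80)},
                          {str(i): y_true[i] for i in range(80)})
        matrix = np.array(report.confusion)
        assert matrix.trace() / matrix.sum() == pytest.approx(report.accuracy_substage)

    def test_substage_never_beats_stage_accuracy(self):
        rng = random.Random(31)
        for _ in range(200):
            n = rng.randint(1, 40)
            gold = {str(i): rng.choice(LABELS) for i in range(n)}
            pred = {str(i): rng.choice(LABELS) for i in range(n)}
            report = evaluate(pred, gold)
            assert report.accuracy_substage <= report.accuracy_stage + 1e-12

    def test_size_only_view_from_results(self):
        result = TStageResult(label=TLabel.T3, size_component=TLabel.T1C,
                              involvement_component=TLabel.T3)
        report = evaluate({"a": result}, {"a": "T3"})
        assert report.accuracy_substage == 1.0
        assert report.accuracy_size_only == 0.0

    def test_plain_labels_have_null_size_view(self):
        report = evaluate({"a": "T3"}, {"a": "T3"})
        assert report.accuracy_size_only is None

    def test_id_mismatch_is_reported(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate({"a": "T3"}, {"b": "T3"})

    def test_collapse_map(self):
        assert collapse_stage("T1b") == "T1"
        assert collapse_stage("T2") == "T2" == collapse_stage("T2b")
        assert collapse_stage("Tx") == "Tx"


def _primary(size=None, structures=(), presence=()):
    from pulmostage.tstage_classifier import default_decision_table
    table = default_decision_table()
    return TumorFinding(
        role=FindingRole.PRIMARY, size_mm=size,
        involvement=[table.involvement_item(s) for s in structures],
        presence=list(presence))


class TestDiffFindings:
    def _gold(self, finding):
        return GoldRecord(report_id="r", label="T1c", planted=[finding])

    def test_exact_match_empty_diff(self):
        f = _primary(size=30.0)
        gold = GoldRecord(report_id="r", label="T1c", planted=[f])
        assert diff_findings([f], gold) == []

    def test_pleural_thickening_size_confusion_is_one_size_discrepancy(self):
        gold = GoldRecord(report_id="r", label="T1c",
                          planted=[_primary(size=30.0)])
        diffs = diff_findings([_primary(size=86.0)], gold)
        assert len(diffs) == 1
        assert diffs[0].component == "size"

    def test_missing_involvement_reported(self):
        gold = GoldRecord(report_id="r", label="T3",
                          planted=[_primary(size=30.0, structures=["chest_wall"])])
        diffs = diff_findings([_primary(size=30.0)], gold)
        assert [d.component for d in diffs] == ["involvement"]
        assert "missing chest_wall" in diffs[0].detail

    def test_spurious_presence_reported(self):
        gold = GoldRecord(report_id="r", label="T1c", planted=[_primary(size=30.0)])
        pred = [_primary(size=30.0, presence=[
            PresenceItem(kind=PresenceKind.POST_OBSTRUCTIVE_ATELECTASIS)])]
        diffs = diff_findings(pred, gold)
        assert [d.component for d in diffs] == ["presence"]
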