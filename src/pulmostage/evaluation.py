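"""Scoring predictions against gold T-substage labels.

Three accuracy views are reported: substage accuracy (exact label match,
with the bare label T2 as its own class), stage accuracy (labels collapsed
to T1/T2/T3/T4), and size-only accuracy (the label each report would have
received from the size component alone).  Per-class precision/recall/F1
use one-vs-rest counts from the confusion matrix; a metric whose
denominator is zero is reported as null rather than zero.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, Field

from .annotation_model import (
    FindingRole,
    PresenceKind,
    TLabel,
    TStageResult,
    TumorFinding,
    t_rank,
)
from .synthetic_corpus import GoldRecord

#: substage -> collapsed stage
STAGE_COLLAPSE = {
    "Tx": "Tx",
    "T1a": "T1", "T1b": "T1", "T1c": "T1",
    "T2": "T2", "T2a": "T2", "T2b": "T2",
    "T3": "T3", "T4": "T4",
}


def collapse_stage(label: TLabel | str) -> str:
    return STAGE_COLLAPSE[str(label.value if isinstance(label, TLabel) else label)]


class ClassMetrics(BaseModel):
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    support: int = 0


class EvalReport(BaseModel):
    accuracy_substage: float = Field(ge=0, le=1)
    accuracy_stage: float = Field(ge=0, le=1)
    accuracy_size_only: Optional[float] = Field(default=None, ge=0, le=1)
    per_class: dict[str, ClassMetrics]
    labels: list[str]
    confusion: list[list[int]]
    n: int = Field(ge=1)


Prediction = Union[TStageResult, TLabel, str]


def _label_of(pred: Prediction) -> str:
    if isinstance(pred, TStageResult):
        return pred.label.value
    return str(pred.value if isinstance(pred, TLabel) else pred)


def evaluate(predictions: Mapping[str, Prediction],
             gold: Mapping[str, TLabel | str],
             size_only: Optional[Mapping[str, TLabel | str]] = None) -> EvalReport:
    """Score a prediction set against gold labels.

    ``predictions`` maps report id to a :class:`TStageResult` or a plain
    label.  The size-only view is computed from the size components when
    full results are given, or from ``size_only`` labels; it is null when
    neither is available.  An id mismatch is an error listing the
    difference.
    """
    pred_ids, gold_ids = set(predictions), set(gold)
    if pred_ids != gold_ids:
        missing = sorted(gold_ids - pred_ids)
        extra = sorted(pred_ids - gold_ids)
        raise ValueError(
            f"prediction/gold id mismatch: missing={missing[:10]} extra={extra[:10]}")
    if not gold:
        raise ValueError("cannot evaluate an empty dataset")

    ids = sorted(gold)
    y_true = [str(gold[i].value if isinstance(gold[i], TLabel) else gold[i]) for i in ids]
    y_pred = [_label_of(predictions[i]) for i in ids]
    n = len(ids)

    # size-only labels
    size_labels: Optional[list[str]] = None
    if all(isinstance(predictions[i], TStageResult) for i in ids):
        size_labels = [
            predictions[i].size_component.value
            if predictions[i].size_component is not None else "Tx"
            for i in ids
        ]
    elif size_only is not None:
        size_labels = [
            str(size_only[i].value if isinstance(size_only[i], TLabel) else size_only[i])
            for i in ids
        ]

    labels = [l for l in ["Tx", "T1a", "T1b", "T1c", "T2", "T2a", "T2b", "T3", "T4"]
              if l in set(y_true) | set(y_pred)]
    index = {l: k for k, l in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[index[t], index[p]] += 1

    per_class: dict[str, ClassMetrics] = {}
    for l, k in index.items():
        tp = int(confusion[k, k])
        support = int(confusion[k, :].sum())
        predicted = int(confusion[:, k].sum())
        precision = tp / predicted if predicted else None
        recall = tp / support if support else None
        if precision is not None and recall is not None and (precision + recall) > 0:
            f1 = 2 * precision * recall / (precision + recall)
        elif precision is not None and recall is not None:
            f1 = 0.0
        else:
            f1 = None
        per_class[l] = ClassMetrics(
            precision=precision, recall=recall, f1=f1, support=support)

    acc_sub = sum(t == p for t, p in zip(y_true, y_pred)) / n
    acc_stage = sum(collapse_stage(t) == collapse_stage(p)
                    for t, p in zip(y_true, y_pred)) / n
    acc_size = (sum(t == s for t, s in zip(y_true, size_labels)) / n
                if size_labels is not None else None)

    return EvalReport(
        accuracy_substage=acc_sub,
        accuracy_stage=acc_stage,
        accuracy_size_only=acc_size,
        per_class=per_class,
        labels=labels,
        confusion=confusion.tolist(),
        n=n,
    )


# ---------------------------------------------------------------------------
# Finding-level discrepancy diff (error triage)
# ---------------------------------------------------------------------------

class Discrepancy(BaseModel):
    component: str  # size | involvement | presence | label
    detail: str


def diff_findings(predicted_findings: Sequence[TumorFinding],
                  gold: GoldRecord) -> list[Discrepancy]:
    """List component mismatches between predicted and planted findings."""
    out: list[Discrepancy] = []

    def primary(findings: Sequence[TumorFinding]) -> Optional[TumorFinding]:
        return next((f for f in findings if f.role is FindingRole.PRIMARY), None)

    p, g = primary(predicted_findings), primary(gold.planted)
    p_size = p.size_mm if p else None
    g_size = g.size_mm if g else None
    if (p_size is None) != (g_size is None) or (
            p_size is not None and abs(p_size - g_size) > 1e-9):
        out.append(Discrepancy(
            component="size", detail=f"gold {g_size} mm vs predicted {p_size} mm"))
    p_inv = {i.structure for i in (p.involvement if p else [])}
    g_inv = {i.structure for i in (g.involvement if g else [])}
    for s in sorted(g_inv - p_inv):
        out.append(Discrepancy(component="involvement", detail=f"missing {s}"))
    for s in sorted(p_inv - g_inv):
        out.append(Discrepancy(component="involvement", detail=f"spurious {s}"))
    p_pres = {i.kind.value for i in (p.presence if p else [])}
    g_pres = {i.kind.value for i in (g.presence if g else [])}
    for s in sorted(g_pres - p_pres):
        out.append(Discrepancy(component="presence", detail=f"missing {s}"))
    for s in sorted(p_pres - g_pres):
        out.append(Discrepancy(component="presence", detail=f"spurious {s}"))
    return out
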