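"""Confusion matrices and the five standard evaluation metrics.

Cells follow the clinical 2x2 convention: a = true positives,
b = false positives, c = false negatives, d = true negatives. Metrics are
percentages: sensitivity/recall a/(a+c), specificity d/(b+d),
precision/PPV a/(a+b), NPV d/(c+d), and F1 = 2PR/(P+R) computed from the
unrounded precision and recall. Values are rounded half-up (the convention
of printed clinical tables, not banker's rounding); a zero denominator
yields an explicit not-applicable marker, never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

NA = None  # explicit not-applicable marker for undefined metrics

METRIC_ROWS = (
    "sensitivity_recall",
    "specificity",
    "precision_ppv",
    "npv",
    "f1",
)


class EvaluationError(ValueError):
    """Prediction/gold vectors that cannot be joined or are malformed."""


@dataclass(frozen=True)
class ConfusionMatrix:
    a: int  # true positives
    b: int  # false positives
    c: int  # false negatives
    d: int  # true negatives

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class MetricsReport:
    sensitivity_recall: Optional[float]
    specificity: Optional[float]
    precision_ppv: Optional[float]
    npv: Optional[float]
    f1: Optional[float]
    total: int

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_ROWS} | {
            "total": self.total
        }


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as printed tables do."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def build_confusion(preds: Sequence[int], golds: Sequence[int]) -> ConfusionMatrix:
    if len(preds) != len(golds):
        raise EvaluationError(
            f"length mismatch: {len(preds)} predictions vs {len(golds)} golds"
        )
    for v in list(preds) + list(golds):
        if v not in (0, 1):
            raise EvaluationError(f"labels must be binary 0/1, got {v!r}")
    a = sum(1 for p, g in zip(preds, golds) if p == 1 and g == 1)
    b = sum(1 for p, g in zip(preds, golds) if p == 1 and g == 0)
    c = sum(1 for p, g in zip(preds, golds) if p == 0 and g == 1)
    d = sum(1 for p, g in zip(preds, golds) if p == 0 and g == 0)
    return ConfusionMatrix(a, b, c, d)


def _pct(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den * 100.0


def compute_metrics(cm: ConfusionMatrix, decimals: int = 1) -> MetricsReport:
    """Compute the five metrics; F1 uses unrounded precision/recall, then
    every defined value is rounded half-up to ``decimals``."""
    sens = _pct(cm.a, cm.a + cm.c)
    spec = _pct(cm.d, cm.b + cm.d)
    prec = _pct(cm.a, cm.a + cm.b)
    npv = _pct(cm.d, cm.c + cm.d)
    if prec is None or sens is None or prec + sens == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    rounded = [
        None if v is None else round_half_up(v, decimals)
        for v in (sens, spec, prec, npv, f1)
    ]
    return MetricsReport(*rounded, total=cm.total)


def evaluate_predictions(
    results: Sequence, golds: Sequence[tuple[str, int]]
) -> tuple[MetricsReport, ConfusionMatrix]:
    """Join classifications to gold labels on report_id (order-independent)
    and evaluate. ``results`` may be DocumentClassification objects or
    (report_id, prediction) pairs."""
    pred_pairs = [
        (r.report_id, r.ischemia) if hasattr(r, "report_id") else (r[0], int(r[1]))
        for r in results
    ]
    gold_map: dict[str, int] = {}
    dupes = []
    for rid, label in golds:
        if rid in gold_map:
            dupes.append(rid)
        gold_map[rid] = int(label)
    pred_ids = [rid for rid, _ in pred_pairs]
    dupes += [rid for rid in set(pred_ids) if pred_ids.count(rid) > 1]
    missing = [rid for rid in pred_ids if rid not in gold_map]
    if dupes or missing:
        problems = []
        if dupes:
            problems.append(f"duplicate report_ids: {sorted(set(dupes))}")
        if missing:
            problems.append(f"report_ids missing from golds: {sorted(missing)}")
        raise EvaluationError("; ".join(problems))
    preds = [p for _, p in pred_pairs]
    gold_vec = [gold_map[rid] for rid in pred_ids]
    cm = build_confusion(preds, gold_vec)
    return compute_metrics(cm), cm


def _fmt(v: Optional[float]) -> str:
    if v is None:
        return "NA"
    if v == int(v):
        return f"{int(v)}%"
    return f"{v}%"


def report_frame(
    reports: dict[str, tuple[MetricsReport, ConfusionMatrix]]
) -> pd.DataFrame:
    """One column per model/run, rows mirroring the standard layout:
    the four cells, total, then the five metrics."""
    rows = ["a", "b", "c", "d", "total"] + list(METRIC_ROWS)
    data = {}
    for name, (mr, cm) in reports.items():
        data[name] = [cm.a, cm.b, cm.c, cm.d, cm.total] + [
            getattr(mr, m) for m in METRIC_ROWS
        ]
    return pd.DataFrame(data, index=rows)


def format_report(mr: MetricsReport, cm: ConfusionMatrix, name: str = "model") -> str:
    """Aligned plain-text rendering of one evaluation."""
    lines = [
        f"Evaluation: {name}",
        f"  True positives  (a): {cm.a}",
        f"  False positives (b): {cm.b}",
        f"  False negatives (c): {cm.c}",
        f"  True negatives  (d): {cm.d}",
        f"  Total               : {cm.total}",
        f"  Sensitivity/Recall  : {_fmt(mr.sensitivity_recall)}",
        f"  Specificity         : {_fmt(mr.specificity)}",
        f"  Precision/PPV       : {_fmt(mr.precision_ppv)}",
        f"  NPV                 : {_fmt(mr.npv)}",
        f"  F1                  : {_fmt(mr.f1)}",
    ]
    return "\n".join(lines)
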