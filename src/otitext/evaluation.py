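"""Confusion matrices and balanced (macro-averaged) evaluation metrics.

Conventions, fixed across the package:

* the confusion matrix has predicted classes on rows and gold-standard
  classes on columns, both in the canonical six-class order;
* *balanced precision* and *balanced recall* are unweighted means of the
  per-class precision (diagonal over row sum) and recall (diagonal over
  column sum);
* *balanced F1* is the harmonic mean of balanced precision and balanced
  recall — not the macro-average of per-class F1 scores, which is exposed
  separately as ``macro_f1``;
* a class never predicted (empty row) contributes precision 0 with a
  warning, and likewise an absent gold class for recall;
* reported percentages are rounded to two decimals, half-up.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .classes import CLASS_LABELS, N_CLASSES, OtitisClass, VisitRecord


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding as used in printed result tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """6x6 nonnegative counts: rows predicted, columns gold."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"confusion matrix must be {N_CLASSES}x{N_CLASSES}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    @property
    def n_misclassified(self) -> int:
        return self.total - self.n_correct

    def save_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("predicted\\gold\t" + "\t".join(CLASS_LABELS) + "\n")
            for label, row in zip(CLASS_LABELS, self.counts):
                fh.write(label + "\t" + "\t".join(str(int(c)) for c in row) + "\n")

    @classmethod
    def load_tsv(cls, path) -> "ConfusionMatrix":
        rows = []
        with open(path, encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        body = lines[1:] if not lines[0].split("\t")[1].lstrip("-").isdigit() else lines
        for ln in body:
            parts = ln.split("\t")
            cells = parts[1:] if not parts[0].lstrip("-").isdigit() else parts
            rows.append([int(c) for c in cells])
        return cls(np.asarray(rows))


def confusion_matrix(
    predicted: Sequence[OtitisClass], gold: Sequence[OtitisClass]
) -> ConfusionMatrix:
    """Tally cell (i, j): records predicted class i whose gold class is j."""
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold label vectors must have equal length")
    if not predicted:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for p, g in zip(predicted, gold):
        counts[p.index, g.index] += 1
    return ConfusionMatrix(counts)


def _per_class_ratio(diag: np.ndarray, denom: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros(N_CLASSES)
    for i in range(N_CLASSES):
        if denom[i] == 0:
            warnings.warn(
                f"class {CLASS_LABELS[i]!r}: undefined {what} "
                "(empty denominator); contributing 0",
                stacklevel=3,
            )
        else:
            out[i] = diag[i] / denom[i]
    return out


def per_class_precision(cm: ConfusionMatrix) -> np.ndarray:
    return _per_class_ratio(np.diag(cm.counts), cm.counts.sum(axis=1), "precision")


def per_class_recall(cm: ConfusionMatrix) -> np.ndarray:
    return _per_class_ratio(np.diag(cm.counts), cm.counts.sum(axis=0), "recall")


def accuracy(cm: ConfusionMatrix) -> float:
    """Percentage of records on the diagonal."""
    if cm.total == 0:
        raise ValueError("accuracy undefined for an empty confusion matrix")
    return 100.0 * cm.n_correct / cm.total


def balanced_precision(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("balanced precision undefined for an empty confusion matrix")
    return 100.0 * float(per_class_precision(cm).mean())


def balanced_recall(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("balanced recall undefined for an empty confusion matrix")
    return 100.0 * float(per_class_recall(cm).mean())


def balanced_f1(bp: float, br: float) -> float:
    """Harmonic mean of balanced precision and balanced recall (percent)."""
    if not (0 <= bp <= 100 and 0 <= br <= 100):
        raise ValueError("balanced precision/recall must be percentages in [0, 100]")
    if bp == 0 and br == 0:
        warnings.warn("balanced precision and recall both 0; F1 defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * bp * br / (bp + br)


def macro_f1(cm: ConfusionMatrix) -> float:
    """Secondary output: unweighted mean of per-class F1 scores (percent)."""
    p = per_class_precision(cm)
    r = per_class_recall(cm)
    with np.errstate(invalid="ignore"):
        f1 = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
    return 100.0 * float(f1.mean())


@dataclass
class MetricsReport:
    accuracy: float
    balanced_precision: float
    balanced_recall: float
    balanced_f1: float
    macro_f1: float
    per_class_precision: list[float]
    per_class_recall: list[float]
    n_misclassified: int
    total: int

    def rounded(self, decimals: int = 2) -> dict:
        return {
            "accuracy": round_half_up(self.accuracy, decimals),
            "balanced_precision": round_half_up(self.balanced_precision, decimals),
            "balanced_recall": round_half_up(self.balanced_recall, decimals),
            "balanced_f1": round_half_up(self.balanced_f1, decimals),
            "macro_f1": round_half_up(self.macro_f1, decimals),
            "n_misclassified": self.n_misclassified,
            "total": self.total,
        }

    def to_json(self, path) -> None:
        obj = self.rounded()
        obj["per_class_precision"] = [round_half_up(100 * x) for x in self.per_class_precision]
        obj["per_class_recall"] = [round_half_up(100 * x) for x in self.per_class_recall]
        obj["class_order"] = list(CLASS_LABELS)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=2)


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    bp = balanced_precision(cm)
    br = balanced_recall(cm)
    return MetricsReport(
        accuracy=accuracy(cm),
        balanced_precision=bp,
        balanced_recall=br,
        balanced_f1=balanced_f1(bp, br),
        macro_f1=macro_f1(cm),
        per_class_precision=per_class_precision(cm).tolist(),
        per_class_recall=per_class_recall(cm).tolist(),
        n_misclassified=cm.n_misclassified,
        total=cm.total,
    )


@dataclass
class MisclassifiedRecord:
    record_id: str
    predicted: OtitisClass
    gold: OtitisClass
    fields: dict[str, str]
    tags: list[str]


@dataclass
class ErrorReport:
    records: list[MisclassifiedRecord]
    pair_counts: dict[tuple[str, str], int]  # (predicted, gold) -> count

    @property
    def n_misclassified(self) -> int:
        return len(self.records)

    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for r in self.records:
                fh.write(
                    json.dumps(
                        {
                            "record_id": r.record_id,
                            "predicted": r.predicted.label,
                            "gold": r.gold.label,
                            "fields": r.fields,
                            "tags": r.tags,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )


def error_report(
    records: Sequence[VisitRecord],
    predicted: Sequence[OtitisClass],
    gold: Optional[Sequence[OtitisClass]] = None,
) -> ErrorReport:
    """List every misclassified record with its texts and (predicted, gold) pair."""
    if gold is None:
        gold = [r.gold_label for r in records]
        if any(g is None for g in gold):
            raise ValueError("records without gold labels; pass gold explicitly")
    if not (len(records) == len(predicted) == len(gold)):
        raise ValueError("records, predictions and gold labels must align")
    errs: list[MisclassifiedRecord] = []
    pair_counts: dict[tuple[str, str], int] = {}
    for rec, p, g in zip(records, predicted, gold):
        if p != g:
            errs.append(MisclassifiedRecord(rec.visit_id, p, g, dict(rec.fields), list(rec.tags)))
            key = (p.label, g.label)
            pair_counts[key] = pair_counts.get(key, 0) + 1
    return ErrorReport(records=errs, pair_counts=pair_counts)
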