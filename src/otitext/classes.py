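"""Core domain types for the otitis free-text classification pipeline.

The six diagnostic classes are mutually exclusive and kept in one fixed
canonical order everywhere: confusion-matrix axes, the six output neurons of
every network, and serialized labels all use this order.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional


class OtitisClass(Enum):
    """Diagnostic class of one pediatric visit record.

    Values are the canonical integer indices 0-5; the order is shared by the
    confusion matrix, the network output layer and every serialization.
    """

    NO_OTITIS = 0
    OTITIS_NOT_MEDIA = 1
    OM_NOT_ACUTE = 2
    AOM = 3
    AOM_PERFORATION = 4
    AOM_RECURRENT = 5

    @property
    def index(self) -> int:
        return self.value

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "OtitisClass":
        try:
            return cls[label.upper()]
        except KeyError:
            raise ValueError(f"unknown otitis class label: {label!r}") from None

    @classmethod
    def ordered(cls) -> tuple["OtitisClass", ...]:
        return tuple(sorted(cls, key=lambda c: c.value))


N_CLASSES = len(OtitisClass)

CLASS_LABELS: tuple[str, ...] = tuple(c.label for c in OtitisClass.ordered())


@dataclass
class VisitRecord:
    """One clinical encounter with ordered named free-text fields.

    ``fields`` maps field name (e.g. ``diagnosis``, ``notes``,
    ``prescriptions``) to free text, in insertion order.  ``gold_label`` is
    the adjudicated class when known.  ``tags`` records which confounders the
    synthetic generator injected (empty for real or clean records).
    """

    visit_id: str
    patient_id: str
    pediatrician_id: str
    visit_date: _dt.date
    sex: str  # "male" | "female"
    fields: dict[str, str]
    gold_label: Optional[OtitisClass] = None
    tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.fields or not any(v.strip() for v in self.fields.values()):
            raise ValueError(f"record {self.visit_id}: at least one field must be non-empty")

    def to_json(self) -> str:
        obj = {
            "visit_id": self.visit_id,
            "patient_id": self.patient_id,
            "pediatrician_id": self.pediatrician_id,
            "visit_date": self.visit_date.isoformat(),
            "sex": self.sex,
            "fields": self.fields,
            "gold_label": self.gold_label.label if self.gold_label is not None else None,
            "tags": self.tags,
        }
        return json.dumps(obj, ensure_ascii=False, sort_keys=False)

    @classmethod
    def from_json(cls, line: str) -> "VisitRecord":
        obj = json.loads(line)
        return cls(
            visit_id=obj["visit_id"],
            patient_id=obj["patient_id"],
            pediatrician_id=obj["pediatrician_id"],
            visit_date=_dt.date.fromisoformat(obj["visit_date"]),
            sex=obj["sex"],
            fields=dict(obj["fields"]),
            gold_label=(
                OtitisClass.from_label(obj["gold_label"])
                if obj.get("gold_label") is not None
                else None
            ),
            tags=list(obj.get("tags", [])),
        )


def write_corpus_jsonl(records: Iterable[VisitRecord], path) -> None:
    """Write records as JSON Lines, one visit per line, ISO-8601 dates."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json())
            fh.write("\n")


def read_corpus_jsonl(path) -> list[VisitRecord]:
    with open(path, encoding="utf-8") as fh:
        return [VisitRecord.from_json(line) for line in fh if line.strip()]


def iter_corpus_jsonl(path) -> Iterator[VisitRecord]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                yield VisitRecord.from_json(line)
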