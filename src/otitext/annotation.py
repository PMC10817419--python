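"""Gold-standard support: recurrent-AOM rule, adjudication, inter-rater kappa.

A child's acute otitis media (AOM) is *recurrent* when there are at least
three episodes within six months (183 days) or at least four within twelve
months (365 days), or when the pediatrician explicitly marks the case as
recurrent.  Windows are fixed day counts anchored at each episode date
(closed interval), which keeps the rule exactly testable against an
exhaustive all-windows scan.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score

from .classes import OtitisClass


@dataclass
class RecurrenceRule:
    short_window_days: int = 183
    short_threshold: int = 3
    long_window_days: int = 365
    long_threshold: int = 4

    def __post_init__(self) -> None:
        if min(self.short_threshold, self.long_threshold) < 1:
            raise ValueError("thresholds must be >= 1")
        if min(self.short_window_days, self.long_window_days) < 1:
            raise ValueError("windows must be >= 1 day")


def classify_recurrent(
    episode_dates: Sequence[_dt.date],
    explicit_statement: bool = False,
    rule: RecurrenceRule | None = None,
) -> bool:
    """True iff the explicit statement is present or an anchored window fires.

    Each episode date anchors the closed windows [t, t + window - 1 day];
    the rule fires when any short window holds >= short_threshold episodes
    or any long window holds >= long_threshold.
    """
    if explicit_statement:
        return True
    rule = rule or RecurrenceRule()
    dates = sorted(episode_dates)
    n = len(dates)
    for i, start in enumerate(dates):
        short_end = start + _dt.timedelta(days=rule.short_window_days - 1)
        long_end = start + _dt.timedelta(days=rule.long_window_days - 1)
        in_short = in_long = 0
        for d in dates[i:]:
            if d <= short_end:
                in_short += 1
            if d <= long_end:
                in_long += 1
        if in_short >= rule.short_threshold or in_long >= rule.long_threshold:
            return True
    return False


@dataclass
class AnnotationPair:
    record_id: str
    label_a: OtitisClass
    label_b: OtitisClass
    adjudicated: Optional[OtitisClass] = None


@dataclass
class AdjudicationReport:
    final_labels: dict[str, OtitisClass]
    n_pairs: int
    n_disagreements: int

    @property
    def disagreement_rate(self) -> float:
        return self.n_disagreements / self.n_pairs if self.n_pairs else 0.0


def adjudicate(pairs: Sequence[AnnotationPair]) -> AdjudicationReport:
    """Resolve dual-review labels: shared label on agreement, else the third
    reviewer's adjudicated label (which must be present)."""
    final: dict[str, OtitisClass] = {}
    n_dis = 0
    for p in pairs:
        if p.label_a == p.label_b:
            final[p.record_id] = p.label_a
        else:
            n_dis += 1
            if p.adjudicated is None:
                raise ValueError(
                    f"record {p.record_id}: reviewers disagree "
                    f"({p.label_a.label} vs {p.label_b.label}) and no adjudicated label given"
                )
            final[p.record_id] = p.adjudicated
    return AdjudicationReport(final_labels=final, n_pairs=len(pairs), n_disagreements=n_dis)


@dataclass
class KappaConfig:
    weighting: str = "linear"  # linear | quadratic | unweighted

    def __post_init__(self) -> None:
        if self.weighting not in ("linear", "quadratic", "unweighted"):
            raise ValueError(f"unknown kappa weighting {self.weighting!r}")


def weighted_cohens_kappa(
    labels_a: Sequence[OtitisClass],
    labels_b: Sequence[OtitisClass],
    config: KappaConfig | None = None,
) -> float:
    """Weighted Cohen's kappa over the six-class canonical order.

    Disagreement weights follow the configured scheme over class indices.
    The degenerate case (chance disagreement zero, e.g. one rater constant
    and kappa undefined) returns 0.0 with a warning.
    """
    cfg = config or KappaConfig()
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    if not labels_a:
        raise ValueError("label vectors must be non-empty")
    a = [c.index for c in labels_a]
    b = [c.index for c in labels_b]
    if a == b:
        return 1.0  # perfect agreement, defined even when chance agreement is 1
    weights = None if cfg.weighting == "unweighted" else cfg.weighting
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        kappa = cohen_kappa_score(
            a, b, labels=[c.index for c in OtitisClass.ordered()], weights=weights
        )
    if not np.isfinite(kappa):
        warnings.warn(
            "degenerate kappa (zero chance disagreement); returning 0.0",
            stacklevel=2,
        )
        return 0.0
    return float(kappa)


def read_annotations_tsv(path) -> list[AnnotationPair]:
    """record_id, label_a, label_b, adjudicated (empty when agreeing)."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rid, la, lb = parts[0], parts[1], parts[2]
            adj = parts[3] if len(parts) > 3 and parts[3] else None
            pairs.append(
                AnnotationPair(
                    rid,
                    OtitisClass.from_label(la),
                    OtitisClass.from_label(lb),
                    OtitisClass.from_label(adj) if adj else None,
                )
            )
    return pairs


def write_annotations_tsv(pairs: Sequence[AnnotationPair], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            adj = p.adjudicated.label if p.adjudicated else ""
            fh.write(f"{p.record_id}\t{p.label_a.label}\t{p.label_b.label}\t{adj}\n")
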