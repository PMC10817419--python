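"""Training/validation/test sampling with per-pediatrician stratification.

The training set is drawn from historical records (strictly before the
cutoff date); validation and test come from the later period.  Within every
set the per-pediatrician record shares reproduce the full-corpus shares by
an exact largest-remainder quota, and optionally every pediatrician with at
least one eligible record in a set's period contributes at least one
record.  Validation and test are carved disjointly out of one seeded
permutation of each pediatrician's post-cutoff records.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .classes import VisitRecord
from .quota import largest_remainder

SET_NAMES = ("train", "validation", "test")


class InfeasibleSplitError(ValueError):
    """Requested sizes cannot be met; the message names the binding constraint."""


@dataclass
class SplitConfig:
    set_sizes: dict[str, int] = field(
        default_factory=lambda: {"train": 1000, "validation": 500, "test": 500}
    )
    min_records_per_set: int = 500
    historical_cutoff: _dt.date = _dt.date(2008, 1, 1)
    ensure_pediatrician_coverage: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.min_records_per_set < 1:
            raise ValueError("min_records_per_set must be >= 1")
        if set(self.set_sizes) != set(SET_NAMES):
            raise ValueError(f"set_sizes must have exactly the keys {SET_NAMES}")
        for name, size in self.set_sizes.items():
            if size < self.min_records_per_set:
                raise InfeasibleSplitError(
                    f"set {name!r} size {size} is below min_records_per_set "
                    f"({self.min_records_per_set})"
                )


@dataclass
class SplitAssignment:
    """record_id -> set name; unsampled records are absent."""

    assignment: dict[str, str]

    def ids(self, set_name: str) -> list[str]:
        return [r for r, s in self.assignment.items() if s == set_name]

    def subset(self, corpus: list[VisitRecord], set_name: str) -> list[VisitRecord]:
        return [r for r in corpus if self.assignment.get(r.visit_id) == set_name]

    def sizes(self) -> dict[str, int]:
        out = {s: 0 for s in SET_NAMES}
        for s in self.assignment.values():
            out[s] += 1
        return out

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rid, s in self.assignment.items():
                fh.write(f"{rid}\t{s}\n")

    @classmethod
    def load(cls, path) -> "SplitAssignment":
        assignment = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                rid, s = line.rstrip("\n").split("\t")
                assignment[rid] = s
        return cls(assignment)


def _coverage_quota(
    size: int, shares: np.ndarray, capacity: np.ndarray, coverage: bool, what: str
) -> np.ndarray:
    """Largest-remainder quota adjusted for capacity and coverage.

    Deterministic: redistribution always goes to the lowest-index
    pediatrician with the most spare capacity.
    """
    q = np.asarray(largest_remainder(size, shares), dtype=int)
    if coverage:
        eligible = capacity > 0
        if size < int(eligible.sum()):
            raise InfeasibleSplitError(
                f"{what}: size {size} cannot cover all {int(eligible.sum())} "
                "pediatricians with eligible records"
            )
        q[eligible & (q == 0)] = 1
        while q.sum() > size:
            big = np.where(q > 1)[0]
            if big.size == 0:
                big = np.where(q == 1)[0]
            j = big[np.argmax(q[big])]
            q[j] -= 1
    # cap at capacity, redistribute the deficit to pediatricians with spare
    over = q > capacity
    deficit = int((q[over] - capacity[over]).sum())
    q = np.minimum(q, capacity)
    while deficit > 0:
        spare = capacity - q
        if spare.max() <= 0:
            raise InfeasibleSplitError(
                f"{what}: only {int(capacity.sum())} eligible records for size {size}"
            )
        j = int(np.argmax(spare))
        q[j] += 1
        deficit -= 1
    return q


def stratified_split(corpus: list[VisitRecord], config: SplitConfig) -> SplitAssignment:
    """Assign records to train/validation/test per the stratified design."""
    config.validate()
    peds = sorted({r.pediatrician_id for r in corpus})
    ped_idx = {p: i for i, p in enumerate(peds)}
    n_ped = len(peds)

    total_counts = np.zeros(n_ped, dtype=int)
    pre: list[list[VisitRecord]] = [[] for _ in range(n_ped)]
    post: list[list[VisitRecord]] = [[] for _ in range(n_ped)]
    for r in corpus:
        i = ped_idx[r.pediatrician_id]
        total_counts[i] += 1
        (pre if r.visit_date < config.historical_cutoff else post)[i].append(r)

    shares = total_counts / total_counts.sum()
    pre_cap = np.array([len(x) for x in pre])
    post_cap = np.array([len(x) for x in post])

    sizes = config.set_sizes
    if pre_cap.sum() < sizes["train"]:
        raise InfeasibleSplitError(
            f"only {int(pre_cap.sum())} records before the cutoff "
            f"{config.historical_cutoff.isoformat()} for a training set of {sizes['train']}"
        )
    if post_cap.sum() < sizes["validation"] + sizes["test"]:
        raise InfeasibleSplitError(
            f"only {int(post_cap.sum())} records on/after the cutoff for "
            f"validation+test of {sizes['validation'] + sizes['test']}"
        )

    cov = config.ensure_pediatrician_coverage
    q_train = _coverage_quota(sizes["train"], shares, pre_cap, cov, "train")
    q_val = _coverage_quota(sizes["validation"], shares, post_cap, cov, "validation")
    q_test = _coverage_quota(
        sizes["test"], shares, post_cap - q_val, cov, "test"
    )

    rng = np.random.default_rng(config.seed)
    assignment: dict[str, str] = {}
    for i in range(n_ped):
        pre_ids = sorted(r.visit_id for r in pre[i])
        perm = rng.permutation(len(pre_ids))
        for j in perm[: q_train[i]]:
            assignment[pre_ids[j]] = "train"
        post_ids = sorted(r.visit_id for r in post[i])
        perm = rng.permutation(len(post_ids))
        for j in perm[: q_val[i]]:
            assignment[post_ids[j]] = "validation"
        for j in perm[q_val[i]: q_val[i] + q_test[i]]:
            assignment[post_ids[j]] = "test"
    return SplitAssignment(assignment)
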