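"""Largest-remainder (Hamilton) apportionment.

Used wherever the pipeline promises exact, deterministic counts: class
quotas in the synthetic generator and per-pediatrician quotas in the
train/validation/test split.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def largest_remainder(total: int, proportions: Sequence[float]) -> list[int]:
    """Apportion ``total`` integer units according to ``proportions``.

    Each bucket first receives the floor of its exact quota; the leftover
    units go to the buckets with the largest fractional remainders, ties
    broken by lower bucket index.  The result always sums to ``total``.

    Raises ``ValueError`` if proportions are negative or do not sum to 1
    within 1e-9 (they are not renormalized silently).
    """
    if total < 0:
        raise ValueError("total must be nonnegative")
    p = np.asarray(proportions, dtype=float)
    if p.size == 0:
        if total:
            raise ValueError("cannot apportion a positive total over zero buckets")
        return []
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1 (got {p.sum()!r})")
    exact = total * p
    counts = np.floor(exact).astype(int)
    leftover = total - int(counts.sum())
    if leftover:
        remainders = exact - counts
        # stable sort on (-remainder) keeps lower index first among ties
        order = np.argsort(-remainders, kind="stable")
        counts[order[:leftover]] += 1
    return counts.tolist()


def quota_from_counts(total: int, counts: Sequence[int]) -> list[int]:
    """Largest-remainder quota using observed counts as the proportion source."""
    c = np.asarray(counts, dtype=float)
    s = c.sum()
    if s <= 0:
        raise ValueError("counts must sum to a positive value")
    return largest_remainder(total, c / s)
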