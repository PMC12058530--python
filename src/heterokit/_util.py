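"""Shared helpers: half-up rounding, percentage formatting, interval arithmetic.

All genomic intervals in this package are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import decimal
from typing import Iterable, Sequence

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at `ndigits` decimals (146.375 -> 146.38).

    Python's builtin round() is banker's rounding; printed summary tables in
    genome reports conventionally use half-up.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def percent_ratio(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage k/n * 100, rounded half-up to `ndigits` decimals.

    Used for every printed count ratio (e.g. 79/114 -> 69.3).
    """
    if denominator == 0:
        raise ValueError("percent_ratio: denominator is zero")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def merge_intervals(
    intervals: Iterable[tuple[int, int]], max_gap: int = 0
) -> list[tuple[int, int]]:
    """Merge intervals whose gap is <= max_gap; returns sorted disjoint list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"malformed interval [{s}, {e})")
        if out and s - out[-1][1] <= max_gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of overlap between two half-open intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Interval Jaccard index: |a∩b| / |a∪b|."""
    inter = interval_overlap(a, b)
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def total_covered(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bp covered by a possibly-overlapping interval set."""
    merged = merge_intervals(intervals) if intervals else []
    return sum(e - s for s, e in merged)


def child_seed(seed: int, offset: int) -> int:
    """Derive a sub-generator seed by fixed offset, kept below 2**31.

    Each feature class draws from its own child generator so that enabling or
    disabling one class does not perturb the randomness of the others.
    """
    return int((int(seed) * 100003 + offset) % (2**31 - 1))


def child_rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, offset))


def as_sorted_disjoint(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Validate that intervals are non-overlapping; return them sorted."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError(f"intervals overlap: [{s1},{e1}) and [{s2},{e2})")
    return ivs
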