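"""Shared numeric and interval helpers.

All thresholding in the package (footprint background cut-offs,
conservation cut-offs) goes through :func:`quantile` so that a single
quantile convention is used everywhere.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

Interval = tuple[int, int]


def quantile(values: Iterable[float], q: float) -> float:
    """Percentile with linear interpolation between order statistics.

    Parameters
    ----------
    values : array-like of float
        Sample values; must be non-empty and finite.
    q : float
        Percentile in [0, 100].
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.size == 0:
        raise ValueError("quantile of empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("quantile input contains non-finite values")
    if not 0.0 <= q <= 100.0:
        raise ValueError(f"percentile must be in [0, 100], got {q}")
    return float(np.percentile(arr, q, method="linear"))


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of half-open intervals as a sorted list of disjoint intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def subtract_intervals(span: Interval, intervals: Sequence[Interval]) -> list[Interval]:
    """`span` minus the union of `intervals`, as sorted disjoint intervals."""
    s0, e0 = span
    out: list[Interval] = []
    pos = s0
    for s, e in merge_intervals(intervals):
        s, e = max(s, s0), min(e, e0)
        if e <= s:
            continue
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < e0:
        out.append((pos, e0))
    return out


def total_length(intervals: Sequence[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))
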