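"""Arithmetic on 0-based half-open integer intervals ``(start, end)``.

All internal genomic and residue coordinates in this package are 0-based
half-open; these helpers operate on plain ``(start, end)`` tuples so that
chromosome/strand bookkeeping stays at the caller.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or abutting intervals into a disjoint union."""
    out: List[Interval] = []
    for s, e in sorted(intervals):
        if s >= e:
            raise ValueError(f"empty interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(intervals: Iterable[Interval], region: Interval) -> List[Interval]:
    """Remove ``region`` from a disjoint union, trimming partial overlaps."""
    rs, re_ = region
    out: List[Interval] = []
    for s, e in intervals:
        if e <= rs or s >= re_:
            out.append((s, e))
            continue
        if s < rs:
            out.append((s, rs))
        if e > re_:
            out.append((re_, e))
    return out


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Intersection of two disjoint sorted unions."""
    a = list(a)
    b = list(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def covers(intervals: Iterable[Interval], region: Interval) -> bool:
    """True if the union of ``intervals`` fully contains ``region``."""
    return total_length(intersect(merge(intervals), [region])) == region[1] - region[0]


def overlaps(intervals: Iterable[Interval], region: Interval) -> bool:
    rs, re_ = region
    return any(s < re_ and e > rs for s, e in intervals)
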