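"""Small helpers for 0-based half-open genomic intervals."""
from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, disjoint list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Intersection of two interval sets (each need not be disjoint)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def point_in_intervals(pos: int, intervals: Iterable[Interval]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def dilate_intervals(intervals: Iterable[Interval], flank: int,
                     bound: int | None = None) -> list[Interval]:
    """Widen each interval by ``flank`` on both sides, clipped to [0, bound)."""
    out = []
    for s, e in intervals:
        s2 = max(0, s - flank)
        e2 = e + flank if bound is None else min(bound, e + flank)
        out.append((s2, e2))
    return merge_intervals(out)


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def interval_positions(intervals: Sequence[Interval]):
    """Iterate every position covered by a (merged) interval set."""
    for s, e in merge_intervals(intervals):
        yield from range(s, e)
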