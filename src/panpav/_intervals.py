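"""Half-open interval arithmetic shared by contig classification and coverage.

All intervals are 0-based, half-open ``[start, end)`` tuples of ints.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted list of disjoint intervals.

    Touching intervals (end == next start) are merged; empty intervals are dropped.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            prev_s, prev_e = merged[-1]
            merged[-1] = (prev_s, max(prev_e, e))
        else:
            merged.append((s, e))
    return merged


def complement(intervals: Sequence[Interval], start: int, end: int) -> list[Interval]:
    """Gaps of ``[start, end)`` not covered by the (arbitrary) input intervals."""
    if end <= start:
        return []
    gaps: list[Interval] = []
    cursor = start
    for s, e in merge_intervals(intervals):
        s = max(s, start)
        e = min(e, end)
        if e <= s:
            continue
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < end:
        gaps.append((cursor, end))
    return gaps


def covered_length(intervals: Iterable[Interval], start: int, end: int) -> int:
    """Number of bases of ``[start, end)`` overlapped by at least one interval."""
    total = 0
    for s, e in merge_intervals(intervals):
        total += max(0, min(e, end) - max(s, start))
    return total
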