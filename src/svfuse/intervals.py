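"""Sorted inclusive-interval arithmetic on flattened coordinates.

Intervals are ``(start, end)`` tuples, 0-based and inclusive at both ends.
These primitives back the base-pair similarity metrics and the segment
projection, so they are implemented directly rather than delegated.
"""

from __future__ import annotations

from svfuse.errors import DataError


def merge(intervals) -> list[tuple[int, int]]:
    """Merge overlapping or abutting intervals into a sorted disjoint list."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if s > e:
            raise DataError(f"invalid interval ({s}, {e})")
        if out and s <= out[-1][1] + 1:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def coverage(merged) -> int:
    """Total bp covered by a disjoint interval list."""
    return sum(e - s + 1 for s, e in merged)


def intersect(a, b) -> list[tuple[int, int]]:
    """Intersection of two sorted disjoint interval lists."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp overlap of two single inclusive intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def validate_disjoint_sorted(intervals) -> None:
    """Raise unless intervals are sorted and pairwise non-overlapping."""
    prev_end = None
    for s, e in intervals:
        if s > e:
            raise DataError(f"invalid interval ({s}, {e})")
        if prev_end is not None and s <= prev_end:
            raise DataError("intervals overlap or are unsorted")
        prev_end = e
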