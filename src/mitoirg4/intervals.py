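"""Half-open interval arithmetic on linear and circular coordinates.

All intervals are 0-based half-open ``(start, end)`` tuples. On a circular
genome of length ``L`` an interval may have ``end > L``, meaning it wraps
past the origin; ``start`` is always in ``[0, L)`` and ``end - start <= L``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of linear intervals: sorted, overlapping/adjacent runs fused."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def complement(intervals: Iterable[Interval], length: int) -> list[Interval]:
    """Gaps of ``[0, length)`` not covered by ``intervals``."""
    out: list[Interval] = []
    pos = 0
    for s, e in merge(intervals):
        if s > pos:
            out.append((pos, min(s, length)))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


def intersect_length(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def overlap_with_set(iv: Interval, retained: Sequence[Interval]) -> int:
    """Total bases of ``iv`` covered by a set of (merged) intervals."""
    return sum(intersect_length(iv, r) for r in merge(retained))


def linear_pieces(iv: Interval, length: int) -> list[Interval]:
    """Split a possibly wrapping circular interval into linear pieces."""
    s, e = iv
    if e <= length:
        return [(s, e)]
    return [(s, length), (0, e - length)]


def circular_gap(end_a: int, start_b: int, length: int) -> Interval:
    """The interval running from ``end_a`` forward to ``start_b`` on a circle.

    Returned in wrap notation (end may exceed ``length``); zero-length when
    the two positions coincide.
    """
    s = end_a % length
    gap = (start_b - end_a) % length
    return (s, s + gap)


def contains(iv: Interval, pos: int, length: int | None = None) -> bool:
    """Membership test honouring wrap notation when ``length`` is given."""
    s, e = iv
    if length is not None and e > length:
        return pos >= s or pos < e - length
    return s <= pos < e
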