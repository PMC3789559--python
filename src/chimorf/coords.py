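"""Circular-coordinate arithmetic.

All public pipeline coordinates are 1-based inclusive on the forward strand.
A feature or interval on a circular genome may wrap the origin, encoded as
``start > stop``.  These helpers keep the wrap handling in one place.
"""

from __future__ import annotations


def circ_point_dist(a: int, b: int, length: int, circular: bool = True) -> int:
    """Shortest distance in bp between two 1-based positions."""
    d = abs(a - b)
    if circular:
        return min(d, length - d)
    return d


def unwrap(start: int, stop: int, length: int) -> list[tuple[int, int]]:
    """Decompose a (possibly origin-wrapping) interval into linear segments."""
    if start <= stop:
        return [(start, stop)]
    return [(start, length), (1, stop)]


def interval_length(start: int, stop: int, length: int) -> int:
    if start <= stop:
        return stop - start + 1
    return (length - start + 1) + stop


def interval_overlap(a: tuple[int, int], b: tuple[int, int], length: int,
                     circular: bool = True) -> int:
    """Overlap in bp between two 1-based inclusive intervals (wrap-aware)."""
    if not circular and (a[0] > a[1] or b[0] > b[1]):
        raise ValueError("wrapping interval on a linear sequence")
    total = 0
    for s1, e1 in unwrap(*a, length):
        for s2, e2 in unwrap(*b, length):
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def interval_gap(a: tuple[int, int], b: tuple[int, int], length: int,
                 circular: bool = True) -> int:
    """Distance in bp between two intervals; 0 when they overlap or touch.

    On a circle the gap is the shorter of the two directed gaps between the
    facing interval ends.
    """
    if interval_overlap(a, b, length, circular) > 0:
        return 0
    best = None
    for s1, e1 in unwrap(*a, length):
        for s2, e2 in unwrap(*b, length):
            if circular:
                g1 = (s2 - e1 - 1) % length
                g2 = (s1 - e2 - 1) % length
                g = min(g1, g2)
            else:
                g = max(s2 - e1 - 1, s1 - e2 - 1)
            best = g if best is None else min(best, g)
    return best


def point_to_interval_dist(pos: int, iv: tuple[int, int], length: int,
                           circular: bool = True) -> int:
    """Distance from a position to an interval (0 when inside)."""
    return interval_gap((pos, pos), iv, length, circular)
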