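"""Closed 1-based amino-acid intervals.

Every interval in this package is a pair ``(start, end)`` of 1-based,
inclusive residue coordinates, matching the ``38..63`` convention used in
region strings. Conversion to half-open coordinates happens only inside the
arithmetic here, never at module interfaces.
"""

from __future__ import annotations

Interval = tuple[int, int]


def length(iv: Interval) -> int:
    """Number of residues covered; 0 for an empty (start > end) interval."""
    return max(0, iv[1] - iv[0] + 1)


def overlaps(a: Interval, b: Interval) -> bool:
    """True when the two intervals share at least one residue."""
    return a[0] <= b[1] and b[0] <= a[1]


def intersection(a: Interval, b: Interval) -> Interval:
    """Common residues; may be empty (start > end)."""
    return (max(a[0], b[0]), min(a[1], b[1]))


def intersect_all(ivs: list[Interval]) -> Interval:
    """Residues common to every interval (empty when start > end)."""
    if not ivs:
        raise ValueError("cannot intersect an empty list of intervals")
    return (max(s for s, _ in ivs), min(e for _, e in ivs))


def span(ivs: list[Interval]) -> Interval:
    """Smallest interval covering every input (the lateral ends)."""
    if not ivs:
        raise ValueError("cannot span an empty list of intervals")
    return (min(s for s, _ in ivs), max(e for _, e in ivs))


def overlap_len(a: Interval, b: Interval) -> int:
    return length(intersection(a, b))


def jaccard(a: Interval, b: Interval) -> float:
    """Jaccard index of the two residue sets (0 when disjoint)."""
    inter = overlap_len(a, b)
    union = length(a) + length(b) - inter
    return inter / union if union else 0.0


def clip(iv: Interval, lo: int, hi: int) -> Interval:
    """Clip to [lo, hi]; result may be empty."""
    return (max(iv[0], lo), min(iv[1], hi))
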