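"""Genome interval algebra on BED-style half-open coordinates.

All intervals are 0-based half-open ``[start, end)``. A 1-based point
position ``p`` overlaps an interval iff ``start <= p - 1 < end``.

These primitives back every overlap query in the package and are
property-tested against a quadratic brute-force oracle, so they are kept
deliberately simple: sorted sweeps, no trees.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "Interval",
    "sort_intervals",
    "merge",
    "intersect",
    "subtract",
    "find_overlaps",
    "point_lookup",
    "coverage_bp",
]


@dataclass(frozen=True)
class Interval:
    """A half-open genomic interval with optional score and label."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains_point(self, pos: int) -> bool:
        """True if the 1-based point ``pos`` lies inside this interval."""
        return self.start <= pos - 1 < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def sort_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def _by_chrom(intervals: Iterable[Interval]) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = defaultdict(list)
    for iv in intervals:
        out[iv.chrom].append(iv)
    for ivs in out.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
    return out


def merge(intervals: Iterable[Interval], gap: int = 0) -> list[Interval]:
    """Merge overlapping/abutting intervals; intervals whose gap is
    <= ``gap`` base pairs are joined. Scores and labels are dropped."""
    out: list[Interval] = []
    for chrom, ivs in sorted(_by_chrom(intervals).items()):
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(Interval(chrom, cur_start, cur_end))
    return out


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Base-pair intersection of the two (independently merged) sets."""
    a_m, b_m = merge(a) if a else [], merge(b) if b else []
    by_b = _by_chrom(b_m)
    out: list[Interval] = []
    for iv in a_m:
        for other in by_b.get(iv.chrom, ()):
            if other.start >= iv.end:
                break
            if other.end <= iv.start:
                continue
            out.append(
                Interval(iv.chrom, max(iv.start, other.start), min(iv.end, other.end))
            )
    return sort_intervals(out)


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Base pairs of ``a`` not covered by ``b`` (both merged first)."""
    a_m = merge(a) if a else []
    b_by = _by_chrom(merge(b) if b else [])
    out: list[Interval] = []
    for iv in a_m:
        cursor = iv.start
        for other in b_by.get(iv.chrom, ()):
            if other.end <= cursor:
                continue
            if other.start >= iv.end:
                break
            if other.start > cursor:
                out.append(Interval(iv.chrom, cursor, other.start))
            cursor = max(cursor, other.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(Interval(iv.chrom, cursor, iv.end))
    return sort_intervals(out)


def find_overlaps(
    a: Sequence[Interval], b: Sequence[Interval]
) -> list[tuple[int, int]]:
    """All index pairs ``(i, j)`` with ``a[i]`` overlapping ``b[j]``.

    Indices refer to input order. Sweep over per-chromosome sorted views.
    """
    a_idx: dict[str, list[tuple[int, Interval]]] = defaultdict(list)
    b_idx: dict[str, list[tuple[int, Interval]]] = defaultdict(list)
    for i, iv in enumerate(a):
        a_idx[iv.chrom].append((i, iv))
    for j, iv in enumerate(b):
        b_idx[iv.chrom].append((j, iv))
    hits: list[tuple[int, int]] = []
    for chrom, a_list in a_idx.items():
        b_list = sorted(b_idx.get(chrom, ()), key=lambda t: t[1].start)
        if not b_list:
            continue
        for i, iv in a_list:
            for j, other in b_list:
                if other.start >= iv.end:
                    break
                if other.end > iv.start:
                    hits.append((i, j))
    hits.sort()
    return hits


def point_lookup(
    intervals: Sequence[Interval], chrom: str, pos: int
) -> list[Interval]:
    """All intervals containing the 1-based point ``pos``."""
    return [
        iv for iv in intervals if iv.chrom == chrom and iv.contains_point(pos)
    ]


def coverage_bp(intervals: Iterable[Interval]) -> int:
    """Total distinct base pairs covered."""
    ivs = list(intervals)
    if not ivs:
        return 0
    return sum(len(iv) for iv in merge(ivs))
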