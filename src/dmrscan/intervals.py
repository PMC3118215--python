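"""Genomic interval algebra.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Dialects that are 1-based inclusive (GFF, some UCSC table dumps) are converted
at the I/O boundary only (see :mod:`dmrscan.genome`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "intersect",
    "union",
    "gap",
    "distance",
    "subtract",
    "total_length",
    "IntervalIndex",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def expanded(self, flank: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, max(0, self.start - flank), self.end + flank)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def intersect(a: GenomicInterval, b: GenomicInterval) -> GenomicInterval | None:
    """Intersection of two intervals, or None when they do not overlap."""
    if not a.overlaps(b):
        return None
    return GenomicInterval(a.chrom, max(a.start, b.start), min(a.end, b.end))


def union(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Disjoint sorted union; abutting intervals are merged."""
    ivs = sorted(intervals)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def gap(a: GenomicInterval, b: GenomicInterval) -> GenomicInterval | None:
    """The interval strictly between a and b; None if they overlap or abut."""
    if a.chrom != b.chrom:
        raise ValueError("gap() requires intervals on the same chromosome")
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    if hi.start <= lo.end:
        return None
    return GenomicInterval(a.chrom, lo.end, hi.start)


def distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Edge-to-edge distance in bp; 0 when overlapping or abutting.

    "Within N bp" throughout this package means ``distance <= N``.
    Intervals on different chromosomes are infinitely far apart.
    """
    if a.chrom != b.chrom:
        return math.inf
    return float(max(a.start - b.end, b.start - a.end, 0))


def subtract(a: GenomicInterval, bs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Parts of ``a`` not covered by any interval in ``bs``."""
    pieces = [a]
    for b in sorted(bs):
        if b.chrom != a.chrom:
            continue
        nxt: list[GenomicInterval] = []
        for p in pieces:
            ov = intersect(p, b)
            if ov is None:
                nxt.append(p)
                continue
            if p.start < ov.start:
                nxt.append(GenomicInterval(p.chrom, p.start, ov.start))
            if ov.end < p.end:
                nxt.append(GenomicInterval(p.chrom, ov.end, p.end))
        pieces = nxt
    return pieces


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total bp covered by the union of the intervals."""
    return sum(iv.length for iv in union(intervals))


class IntervalIndex:
    """Overlap / proximity queries over a fixed interval set.

    Thin per-chromosome wrapper around :class:`intervaltree.IntervalTree`;
    payloads are the positional indices of the input intervals.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.intervals = list(intervals)
        self._trees: dict[str, IntervalTree] = {}
        for i, iv in enumerate(self.intervals):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)

    def overlapping(self, query: GenomicInterval) -> list[int]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(query.start, query.end))

    def within(self, query: GenomicInterval, max_dist: int) -> list[int]:
        """Indices of intervals with edge distance <= max_dist from query."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        lo = max(0, query.start - max_dist - 1)
        hits = tree.overlap(lo, query.end + max_dist + 1)
        out = [
            h.data
            for h in hits
            if distance(query, self.intervals[h.data]) <= max_dist
        ]
        return sorted(out)
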