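"""Genomic intervals and interval arithmetic.

All coordinates are 0-based, half-open ``[start, end)``. These intervals are
the currency of every scanning and counting operation in the package; the
distance convention throughout is *nearest-edge* distance (0 for overlapping
intervals), matching the overlap semantics of the intersection step.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Sequence (contig) name; must be non-empty.
    start, end : int
        0-based half-open bounds; ``0 <= start < end``.
    strand : str
        One of ``+``, ``-``, ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share >= 1 bp (strand-blind)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def edge_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Nearest-edge distance in bp; 0 for overlapping or abutting intervals.

    Raises if the intervals sit on different chromosomes, where the distance
    is undefined.
    """
    if a.chrom != b.chrom:
        raise ValueError("edge_gap undefined across chromosomes")
    return max(a.start - b.end, b.start - a.end, 0)


def is_sorted(intervals: Sequence[GenomicInterval]) -> bool:
    """True iff sorted by (chrom, start)."""
    keys = [(iv.chrom, iv.start) for iv in intervals]
    return all(keys[i] <= keys[i + 1] for i in range(len(keys) - 1))


def require_sorted(intervals: Sequence[GenomicInterval], name: str = "intervals") -> None:
    if not is_sorted(intervals):
        raise ValueError(f"{name} must be sorted by (chrom, start)")


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Members of ``a`` overlapping >= 1 bp with any member of ``b``.

    Both inputs must be sorted by (chrom, start). Output preserves the order
    of ``a``; each retained element appears exactly once.
    """
    require_sorted(a, "a")
    require_sorted(b, "b")
    by_chrom: dict[str, tuple[list[int], list[int]]] = defaultdict(lambda: ([], []))
    for iv in b:
        starts, ends = by_chrom[iv.chrom]
        starts.append(iv.start)
        ends.append(iv.end)
    for starts, ends in by_chrom.values():
        ends.sort()  # starts are already sorted; ends may not be

    kept: list[GenomicInterval] = []
    for iv in a:
        if iv.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[iv.chrom]
        # of intervals with start < iv.end, subtract those ending at/before iv.start
        n_started = bisect_left(starts, iv.end)
        n_done = bisect_right(ends, iv.start)
        if n_started > n_done:
            kept.append(iv)
    return kept


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/abutting intervals into a disjoint sorted set."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged
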