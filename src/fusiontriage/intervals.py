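"""Genomic interval index with closed-interval overlap semantics.

All intervals are 1-based and fully closed, and overlap is defined on
closed intervals: ``[10, 20]`` and ``[20, 30]`` overlap (they share base
20). The index is backed by one :class:`intervaltree.IntervalTree` per
chromosome; the trees use half-open coordinates internally, so every
stored end is shifted by +1 on insertion and queries likewise.

Duplicate intervals are retained: each inserted interval keeps its own
identity even when its coordinates and payload compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable

from intervaltree import IntervalTree

from .errors import ValidationError


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval carrying an opaque payload."""

    chrom: str
    start: int
    end: int
    payload: Any = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome must be non-empty")
        if self.start > self.end:
            raise ValidationError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


class IntervalIndex:
    """Searchable index over a fixed collection of genomic intervals.

    Query results are independent of insertion order (they are returned
    sorted by (start, end, insertion index)) and contain exactly the
    inserted intervals that satisfy the closed-overlap predicate.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._items: list[GenomicInterval] = []
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        if not isinstance(iv, GenomicInterval):
            raise ValidationError(f"not a GenomicInterval: {iv!r}")
        idx = len(self._items)
        self._items.append(iv)
        # store the list index as tree data so duplicates stay distinct
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end + 1, idx
        )

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)

    def query(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """All stored intervals overlapping the closed query [start, end].

        An unknown chromosome yields an empty list, never an error: SV
        partners on unplaced contigs must not abort a run.
        """
        if start > end:
            raise ValidationError(f"query start {start} > end {end}")
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start, end + 1)
        return [self._items[h.data] for h in sorted(hits, key=lambda h: h.data)]

    def at(self, chrom: str, pos: int) -> list[GenomicInterval]:
        """All stored intervals containing the single position ``pos``."""
        return self.query(chrom, pos, pos)


def build_index(intervals: Iterable[GenomicInterval]) -> IntervalIndex:
    """Build an :class:`IntervalIndex` over ``intervals``."""
    return IntervalIndex(intervals)


def query_overlaps(
    index: IntervalIndex, chrom: str, start: int, end: int
) -> list[GenomicInterval]:
    """Intervals i with i.chrom == chrom, i.start <= end and start <= i.end."""
    return index.query(chrom, start, end)


def point_hits(index: IntervalIndex, chrom: str, pos: int) -> list[GenomicInterval]:
    """Equivalent to ``query_overlaps(index, chrom, pos, pos)``."""
    if pos < 1:
        raise ValidationError(f"position must be >= 1, got {pos}")
    return index.at(chrom, pos)
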