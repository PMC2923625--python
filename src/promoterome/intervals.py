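"""Genomic intervals and annotation tracks.

All coordinates are 0-based, half-open ``[start, end)`` in the UCSC table
convention; conversion to 1-based happens only at human-readable output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff *other* lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class AnnotationTrack:
    """A named collection of intervals with optional per-interval class labels.

    Houses RepeatMasker repeats (label = repeat class), CpG islands, CAGE tag
    clusters and similar BED-derived annotations.  Overlap queries are served
    from per-chromosome interval trees built lazily.
    """

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    labels: Optional[list[str]] = None
    _trees: Optional[dict[str, IntervalTree]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.intervals):
            raise ValueError("labels length must match intervals length")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def _tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for i, iv in enumerate(self.intervals):
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
            object.__setattr__(self, "_trees", trees)
        return self._trees.get(chrom, IntervalTree())

    def overlapping(self, query: GenomicInterval) -> list[tuple[GenomicInterval, Optional[str]]]:
        """All (interval, label) pairs overlapping *query* by >= 1 bp."""
        hits = self._tree(query.chrom).overlap(query.start, query.end)
        out = []
        for h in sorted(hits):
            i = h.data
            lab = self.labels[i] if self.labels is not None else None
            out.append((self.intervals[i], lab))
        return out

    def any_overlap(self, query: GenomicInterval) -> bool:
        return bool(self._tree(query.chrom).overlap(query.start, query.end))

    def covers_point(self, chrom: str, pos: int) -> bool:
        """True iff some interval contains the single base at *pos*."""
        return bool(self._tree(chrom).overlap(pos, pos + 1))

    def subset(self, keep: Iterable[bool]) -> "AnnotationTrack":
        keep = list(keep)
        ivs = [iv for iv, k in zip(self.intervals, keep) if k]
        labs = None
        if self.labels is not None:
            labs = [l for l, k in zip(self.labels, keep) if k]
        return AnnotationTrack(self.name, ivs, labs)


def merge_ranges(ranges: Sequence[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    """Merge inclusive integer ranges that overlap or lie within *gap* of each other."""
    if not ranges:
        return []
    srt = sorted(ranges)
    merged = [list(srt[0])]
    for lo, hi in srt[1:]:
        if lo <= merged[-1][1] + gap + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(m) for m in merged]
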