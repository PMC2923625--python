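"""Transcript models and gene clusters.

A gene is a cluster of transcripts that share sequence: either as supplied by
a knownIsoforms-style cluster map, or (fallback) as connected components of
same-strand exonic overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .intervals import GenomicInterval, merge_ranges


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: its locus, optional CDS, ordered exons and gene cluster id."""

    id: str
    locus: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds: Optional[GenomicInterval] = None
    cluster_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.id}: transcript must have >= 1 exon")
        prev_end = None
        for ex in self.exons:
            if not self.locus.contains(ex):
                raise ValueError(f"{self.id}: exon {ex} outside locus {self.locus}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.id}: exons not sorted/disjoint")
            prev_end = ex.end
        if self.cds is not None and not self.locus.contains(self.cds):
            raise ValueError(f"{self.id}: CDS outside locus")

    @property
    def chrom(self) -> str:
        return self.locus.chrom

    @property
    def strand(self) -> str:
        return self.locus.strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Transcription start: locus.start on +, locus.end - 1 on -."""
        return self.locus.start if self.strand == "+" else self.locus.end - 1

    @property
    def first_exon(self) -> GenomicInterval:
        """Strand-aware first exon (lowest coordinate on +, highest on -)."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    @property
    def is_coding(self) -> bool:
        return self.cds is not None


@dataclass
class GeneCluster:
    """All isoforms of one gene; uniform chromosome and strand."""

    cluster_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"cluster {self.cluster_id}: empty")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"cluster {self.cluster_id}: mixed chromosome/strand "
                f"({sorted(chroms)}, {sorted(strands)})"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    def __len__(self) -> int:
        return len(self.transcripts)


def cluster_isoforms(
    transcripts: Sequence[TranscriptModel],
    cluster_map: Optional[Mapping[str, str]] = None,
) -> list[GeneCluster]:
    """Group transcripts into gene clusters.

    With a knownIsoforms-style ``transcript id -> cluster id`` map, clusters
    follow the map exactly (every transcript must be present).  Without a map,
    same-strand transcripts sharing >= 1 bp of exonic sequence are joined by
    single linkage (connected components of exon overlap).
    """
    if cluster_map is not None:
        missing = [t.id for t in transcripts if t.id not in cluster_map]
        if missing:
            raise KeyError(
                f"{len(missing)} transcript(s) absent from cluster map: "
                + ", ".join(sorted(missing)[:10])
            )
        groups: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            groups.setdefault(cluster_map[t.id], []).append(t)
        clusters = []
        for cid in sorted(groups):
            ts = sorted(groups[cid], key=lambda t: (t.locus.start, t.id))
            clusters.append(GeneCluster(cid, ts))
        return clusters
    return _overlap_clusters(transcripts)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _overlap_clusters(transcripts: Sequence[TranscriptModel]) -> list[GeneCluster]:
    """Single-linkage clustering by same-strand exonic overlap (>= 1 bp)."""
    uf = _UnionFind(len(transcripts))
    by_key: dict[tuple[str, str], list[int]] = {}
    for i, t in enumerate(transcripts):
        by_key.setdefault((t.chrom, t.strand), []).append(i)
    for idxs in by_key.values():
        # sweep over exons: transcripts touching one merged exonic blob are linked
        events = []
        for i in idxs:
            for ex in transcripts[i].exons:
                events.append((ex.start, ex.end, i))
        events.sort()
        blob_end = -1
        blob_rep = -1
        for start, end, i in events:
            if start < blob_end:  # overlaps current blob
                uf.union(blob_rep, i)
                blob_end = max(blob_end, end)
            else:
                blob_rep, blob_end = i, end
    groups: dict[int, list[TranscriptModel]] = {}
    for i, t in enumerate(transcripts):
        groups.setdefault(uf.find(i), []).append(t)
    ordered = sorted(
        groups.values(), key=lambda ts: (ts[0].chrom, min(t.locus.start for t in ts))
    )
    clusters = []
    for k, ts in enumerate(ordered, start=1):
        ts = sorted(ts, key=lambda t: (t.locus.start, t.id))
        clusters.append(GeneCluster(f"cluster_{k}", ts))
    return clusters


__all__ = [
    "TranscriptModel",
    "GeneCluster",
    "cluster_isoforms",
    "GenomicInterval",
    "merge_ranges",
]
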