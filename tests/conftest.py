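"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import bisect
from typing import Optional, Sequence

import numpy as np
import pytest

from promoterome.intervals import GenomicInterval
from promoterome.models import GeneCluster, TranscriptModel


def tx(
    tid: str,
    exons: Sequence[tuple[int, int]],
    strand: str = "+",
    chrom: str = "chr1",
    cds: Optional[tuple[int, int]] = None,
) -> TranscriptModel:
    """Terse transcript builder for tests."""
    exons = sorted(exons)
    ivs = tuple(GenomicInterval(chrom, a, b, strand) for a, b in exons)
    locus = GenomicInterval(chrom, exons[0][0], exons[-1][1], strand)
    cds_iv = GenomicInterval(chrom, *cds, strand) if cds else None
    return TranscriptModel(id=tid, locus=locus, exons=ivs, cds=cds_iv)


def oracle_dalfe_pair(cluster: GeneCluster) -> Optional[tuple[str, str]]:
    """Brute-force P1/P2 oracle using raw tuple arithmetic only.

    Enumerates all ordered transcript pairs along the transcription direction
    and returns the first (P1 id, P2 id) satisfying: distinct TSSs, P2's
    first exon inside a gap between consecutive P1 exons, and no first-exon /
    partner-exon overlap.
    """
    strand = cluster.strand
    sign = 1 if strand == "+" else -1

    def tss(t):
        return t.locus.start if strand == "+" else t.locus.end - 1

    def exon_tuples(t):
        return sorted((e.start, e.end) for e in t.exons)

    def fe(t):
        exs = exon_tuples(t)
        return exs[0] if strand == "+" else exs[-1]

    def ov(x, y):
        return x[0] < y[1] and y[0] < x[1]

    ordered = sorted(cluster.transcripts, key=lambda t: (sign * tss(t), t.id))
    for i, p1 in enumerate(ordered):
        for p2 in ordered[i + 1 :]:
            if tss(p1) == tss(p2):
                continue
            f1, f2 = fe(p1), fe(p2)
            exs1 = exon_tuples(p1)
            gaps = [(exs1[k][1], exs1[k + 1][0]) for k in range(len(exs1) - 1)]
            if not any(gs <= f2[0] and f2[1] <= ge for gs, ge in gaps):
                continue
            if any(ov(f2, e) for e in exs1):
                continue
            if any(ov(f1, e) for e in exon_tuples(p2)):
                continue
            return p1.id, p2.id
    return None


def random_cluster(rng: np.random.Generator, max_isoforms: int = 8) -> GeneCluster:
    """A random same-strand cluster with arbitrary exon chains."""
    strand = "+" if rng.random() < 0.5 else "-"
    n = int(rng.integers(1, max_isoforms + 1))
    transcripts = []
    for k in range(n):
        n_ex = int(rng.integers(1, 5))
        pos = int(rng.integers(0, 800))
        exons = []
        for _ in range(n_ex):
            length = int(rng.integers(30, 400))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(50, 900))
        transcripts.append(tx(f"t{k}", exons, strand=strand))
    return GeneCluster("g", transcripts)


def oracle_tag_islands(
    tags: Sequence[int], window: int = 100, min_tags: int = 3
) -> list[tuple[int, int, int]]:
    """Brute-force island oracle: test every possible window position."""
    tags = sorted(tags)
    if len(tags) < min_tags:
        return []
    qualifying = []
    for w in range(tags[0] - window, tags[-1] + 1):
        c = bisect.bisect_left(tags, w + window) - bisect.bisect_left(tags, w)
        if c >= min_tags:
            qualifying.append(w)
    if not qualifying:
        return []
    comps = [[qualifying[0], qualifying[0]]]
    for w in qualifying[1:]:
        if w <= comps[-1][1] + window:  # [w, w+win) overlaps/abuts previous
            comps[-1][1] = w
        else:
            comps.append([w, w])
    out = []
    for a, b in comps:
        inside = [t for t in tags if a <= t <= b + window - 1]
        out.append((inside[0], inside[-1] + 1, len(inside)))
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
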