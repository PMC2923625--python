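"""ChIP-seq tag islands, promoter modification status and CAGE support.

Tag islands follow a density rule: a 100-bp window sliding at 1-bp resolution
qualifies when it covers >= 3 tags; qualifying windows that overlap or abut
are merged and the island is trimmed to its outermost contributing tags.
Promoter status (YES/NONE) is island overlap of a window around the TSS;
CAGE support is strand-matched cluster overlap of a (2*half_window + 1)-nt
interval centered on the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dalfe import DalfePair
from .intervals import AnnotationTrack, GenomicInterval, merge_ranges

YES, NONE = "YES", "NONE"
JOINT_CATEGORIES = ("YES|YES", "YES|NONE", "NONE|YES", "NONE|NONE")


@dataclass(frozen=True)
class TagIsland:
    """A maximal tag-dense segment; islands on one chromosome are disjoint."""

    interval: GenomicInterval
    tag_count: int


@dataclass(frozen=True)
class PairEvidence:
    """Per-pair P1|P2 histone-mark status and CAGE support."""

    pair_id: str
    status_p1: str
    status_p2: str
    cage_p1: Optional[bool] = None
    cage_p2: Optional[bool] = None

    @property
    def joint(self) -> str:
        return f"{self.status_p1}|{self.status_p2}"


def call_tag_islands(
    tags: Sequence[int],
    window: int = 100,
    min_tags: int = 3,
    chrom: str = ".",
) -> list[TagIsland]:
    """Call tag islands from sorted tag positions on one chromosome.

    A window start position w qualifies when [w, w + window) holds >=
    *min_tags* tags.  Qualifying windows whose spans overlap or abut (start
    positions within *window* bp) merge into one island spanning from the
    first to the last contributing tag.
    """
    tags = np.asarray(tags, dtype=np.int64)
    if np.any(np.diff(tags) < 0):
        raise ValueError("tag positions must be sorted ascending")
    k = min_tags
    if tags.size < k:
        return []
    # window-start ranges [lo, hi] (inclusive) that capture a dense tag run
    spans = []
    for i in range(tags.size - k + 1):
        if tags[i + k - 1] - tags[i] <= window - 1:
            spans.append((int(tags[i + k - 1]) - window + 1, int(tags[i])))
    # windows [w, w+window) overlap/abut iff starts are within `window`
    merged = merge_ranges(spans, gap=window - 1)
    islands = []
    for lo, hi in merged:
        inside = tags[(tags >= lo) & (tags <= hi + window - 1)]
        islands.append(
            TagIsland(
                GenomicInterval(chrom, int(inside[0]), int(inside[-1]) + 1),
                int(inside.size),
            )
        )
    return islands


def promoter_status(
    pair: DalfePair,
    islands: Sequence[TagIsland],
    tss_window: int = 1000,
) -> PairEvidence:
    """YES per promoter iff an island overlaps [tss - w, tss + w)."""
    statuses = []
    for tss in (pair.p1_tss, pair.p2_tss):
        q = GenomicInterval(pair.chrom, max(0, tss - tss_window), tss + tss_window)
        hit = any(
            isl.interval.overlaps(q)
            for isl in islands
            if isl.interval.chrom in (pair.chrom, ".")
        )
        statuses.append(YES if hit else NONE)
    return PairEvidence(pair.pair_id, statuses[0], statuses[1])


def tss_tag_profile(
    tss_list: Sequence[tuple[str, int, str]],
    tags: Mapping[str, Sequence[int]],
    flank: int = 5000,
    bin: int = 100,
    min_density: int = 3,
) -> pd.DataFrame:
    """Percent of TSSs with a tag-dense bin at each distance from the TSS.

    *tss_list* holds (chrom, position, strand); *tags* maps chromosome to
    sorted tag positions.  Distances are strand-oriented (negative =
    upstream), binned into [-flank, flank) at *bin* resolution; a bin counts
    for a TSS when it holds >= *min_density* tags.
    """
    if not tss_list:
        raise ValueError("empty TSS list")
    if (2 * flank) % bin != 0:
        raise ValueError("bin must divide 2*flank")
    edges = np.arange(-flank, flank + bin, bin)
    n_bins = edges.size - 1
    qualifying = np.zeros(n_bins, dtype=np.int64)
    for chrom, pos, strand in tss_list:
        positions = np.asarray(tags.get(chrom, ()), dtype=np.int64)
        if positions.size:
            d = positions - pos if strand == "+" else pos - positions
            d = d[(d >= -flank) & (d < flank)]
            counts, _ = np.histogram(d, bins=edges)
        else:
            counts = np.zeros(n_bins, dtype=np.int64)
        qualifying += counts >= min_density
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_center": edges[:-1] + bin / 2,
            "percent": 100.0 * qualifying / len(tss_list),
        }
    )


def distance_by_status(
    pairs: Sequence[DalfePair], evidences: Sequence[PairEvidence]
) -> dict[str, Optional[float]]:
    """Median inter-TSS distance per joint P1|P2 status category."""
    ev = {e.pair_id: e for e in evidences}
    groups: dict[str, list[int]] = {c: [] for c in JOINT_CATEGORIES}
    for pair in pairs:
        e = ev.get(pair.pair_id)
        if e is not None:
            groups[e.joint].append(pair.inter_tss_distance)
    return {
        c: (float(median(d)) if d else None) for c, d in groups.items()
    }


def cage_support(
    pairs: Sequence[DalfePair],
    cage_clusters: AnnotationTrack,
    half_window: int = 100,
) -> tuple[dict[str, bool], float]:
    """Strand-matched CAGE cluster overlap of TSS-centered windows.

    A promoter is supported when a same-strand cluster overlaps the
    (2*half_window + 1)-nt interval centered on its TSS.  Returns per-promoter
    booleans and the overall supported fraction.
    """
    support: dict[str, bool] = {}
    for pair in pairs:
        for which in ("P1", "P2"):
            tss = pair.tss(which)
            q = GenomicInterval(
                pair.chrom, max(0, tss - half_window), tss + half_window + 1
            )
            hit = any(
                iv.strand == pair.strand for iv, _ in cage_clusters.overlapping(q)
            )
            support[pair.promoter_id(which)] = hit
    frac = sum(support.values()) / len(support) if support else 0.0
    return support, frac


def read_tag_positions(path) -> dict[str, np.ndarray]:
    """Read single-base tag positions from a BED file, per chromosome, sorted."""
    from .io import _data_lines, _open_text

    by_chrom: dict[str, list[int]] = {}
    with _open_text(path) as fh:
        for _, fields in _data_lines(fh):
            if len(fields) < 2:
                continue
            by_chrom.setdefault(fields[0], []).append(int(fields[1]))
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}
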