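"""Identification of genes with Distinct Alternative First Exons (DAlFEs).

A gene carries a P1/P2 alternative-promoter pair when, among its isoforms
ordered along the direction of transcription, a downstream transcript's first
exon lies entirely within an intron of an upstream transcript and neither
first exon overlaps any exon of the partner.  Only the first two such
promoters along the DNA are considered per gene.  Pairs are then filtered for
microarray suitability: first exons must exceed 60 bp, be repeat-free, and
carry at least one probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from scipy import stats

from .intervals import AnnotationTrack, GenomicInterval
from .models import GeneCluster, TranscriptModel

# repeat classes ignored when testing repeat association (but NOT when
# filtering first exons for the expression pipeline)
DEFAULT_EXCLUDED_REPEAT_CLASSES = frozenset(
    {"Simple_repeat", "Satellite", "Low_complexity"}
)


@dataclass(frozen=True)
class DalfePair:
    """A gene's P1 (upstream) / P2 (downstream, intronic) promoter pair."""

    cluster_id: str
    p1_transcript: str
    p2_transcript: str
    chrom: str
    strand: str
    p1_first_exon: GenomicInterval
    p2_first_exon: GenomicInterval
    p1_tss: int
    p2_tss: int
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def inter_tss_distance(self) -> int:
        return abs(self.p1_tss - self.p2_tss)

    @property
    def pair_id(self) -> str:
        return self.cluster_id

    def promoter_id(self, which: str) -> str:
        return f"{self.cluster_id}:{which}"

    def tss(self, which: str) -> int:
        return self.p1_tss if which == "P1" else self.p2_tss

    def first_exon_of(self, which: str) -> GenomicInterval:
        return self.p1_first_exon if which == "P1" else self.p2_first_exon

    def with_flags(self, *flags: str) -> "DalfePair":
        return replace(self, flags=self.flags | frozenset(flags))


@dataclass(frozen=True)
class CfeGene:
    """A control gene whose isoforms all share one Constitutive First Exon."""

    cluster_id: str
    shared_first_exon: GenomicInterval
    n_exons: int
    coding_in_first_exon: bool


def first_exon(t: TranscriptModel) -> GenomicInterval:
    """Strand-aware first exon: lowest-coordinate on +, highest on -."""
    return t.first_exon


def _overlaps_any_exon(iv: GenomicInterval, t: TranscriptModel) -> bool:
    return any(iv.overlaps(ex) for ex in t.exons)


def _within_an_intron(iv: GenomicInterval, t: TranscriptModel) -> bool:
    return any(intron.contains(iv) for intron in t.introns)


def identify_dalfe_pair(gene: GeneCluster) -> Optional[DalfePair]:
    """Return the gene's P1/P2 pair, or None when no pair qualifies.

    Transcripts are ordered by TSS along the direction of transcription; the
    first ordered pair with distinct TSSs where the downstream first exon is
    fully contained in an intron of the upstream transcript, and neither first
    exon overlaps any exon of the partner, is returned.  TSS ties between
    candidates are broken by transcript id.
    """
    if len(gene) < 2:
        return None
    sign = 1 if gene.strand == "+" else -1
    ordered = sorted(gene.transcripts, key=lambda t: (sign * t.tss, t.id))
    n = len(ordered)
    for i in range(n - 1):
        for j in range(i + 1, n):
            p1, p2 = ordered[i], ordered[j]
            if p1.tss == p2.tss:
                continue
            fe1, fe2 = p1.first_exon, p2.first_exon
            if not _within_an_intron(fe2, p1):
                continue
            if _overlaps_any_exon(fe2, p1) or _overlaps_any_exon(fe1, p2):
                continue
            return DalfePair(
                cluster_id=gene.cluster_id,
                p1_transcript=p1.id,
                p2_transcript=p2.id,
                chrom=gene.chrom,
                strand=gene.strand,
                p1_first_exon=fe1,
                p2_first_exon=fe2,
                p1_tss=p1.tss,
                p2_tss=p2.tss,
            )
    return None


def apply_filters(
    pair: DalfePair,
    repeats: Optional[AnnotationTrack] = None,
    probes: Optional[Iterable[GenomicInterval]] = None,
    min_exon_len: int = 61,
) -> tuple[DalfePair, bool]:
    """Flag and judge a pair for expression analysis.

    Drops (keep=False) when either first exon is shorter than *min_exon_len*
    (default: <= 60 bp fails), overlaps >= 1 bp of any repeat (all classes),
    or, when *probes* is given, lacks an overlapping probe.  Flags record
    every rule that fired.
    """
    flags: set[str] = set()
    for fe in (pair.p1_first_exon, pair.p2_first_exon):
        if fe.length < min_exon_len:
            flags.add("short_first_exon")
        if repeats is not None and repeats.any_overlap(fe):
            flags.add("repeat_in_first_exon")
    if probes is not None:
        if not isinstance(probes, AnnotationTrack):
            probes = AnnotationTrack("probes", list(probes))
        for fe in (pair.p1_first_exon, pair.p2_first_exon):
            if not probes.any_overlap(fe):
                flags.add("no_probe")
                break
    flagged = pair.with_flags(*flags)
    return flagged, not flags


def classify_first_exon(t: TranscriptModel) -> str:
    """'contains_coding' iff the first exon overlaps the CDS, else 'utr_only'."""
    if t.cds is None:
        return "utr_only"
    return "contains_coding" if t.first_exon.overlaps(t.cds) else "utr_only"


def tss_in_repeat(pair: DalfePair, repeats: AnnotationTrack) -> tuple[bool, bool]:
    """Whether each promoter's TSS base falls inside a repeat interval."""
    return (
        repeats.covers_point(pair.chrom, pair.p1_tss),
        repeats.covers_point(pair.chrom, pair.p2_tss),
    )


def promoter_cpg_status(
    pair: DalfePair, islands: AnnotationTrack, window: int = 500
) -> tuple[bool, bool]:
    """Whether a CpG island overlaps [tss - window, tss + window) per promoter."""
    out = []
    for tss in (pair.p1_tss, pair.p2_tss):
        q = GenomicInterval(pair.chrom, max(0, tss - window), tss + window)
        out.append(islands.any_overlap(q))
    return tuple(out)


@dataclass(frozen=True)
class RepeatAssociation:
    """Contingency of repeat overlap in DAlFE vs CFE first exons."""

    table: tuple[tuple[int, int], tuple[int, int]]
    fold: float
    p_value: float
    dalfe_fraction: float
    cfe_fraction: float


def repeat_association_stats(
    dalfe_first_exons: Sequence[GenomicInterval],
    cfe_first_exons: Sequence[GenomicInterval],
    repeats: AnnotationTrack,
    exclude_classes: frozenset[str] = DEFAULT_EXCLUDED_REPEAT_CLASSES,
) -> RepeatAssociation:
    """Fold difference and Fisher exact test of repeat occurrence.

    Repeats from the excluded classes (simple repeats, satellites, low
    complexity) are ignored; an exon counts as repeat-bearing when it overlaps
    >= 1 bp of any retained repeat.
    """
    if not dalfe_first_exons or not cfe_first_exons:
        raise ValueError("both exon sets must be non-empty")
    if repeats.labels is not None:
        retained = repeats.subset(l not in exclude_classes for l in repeats.labels)
    else:
        retained = repeats
    d_hit = sum(retained.any_overlap(fe) for fe in dalfe_first_exons)
    c_hit = sum(retained.any_overlap(fe) for fe in cfe_first_exons)
    n_d, n_c = len(dalfe_first_exons), len(cfe_first_exons)
    table = ((d_hit, n_d - d_hit), (c_hit, n_c - c_hit))
    pd, pc = d_hit / n_d, c_hit / n_c
    fold = float("inf") if pc == 0 and pd > 0 else (1.0 if pd == pc == 0 else pd / pc)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return RepeatAssociation(table, fold, float(p), pd, pc)


def build_cfe_controls(genes: Sequence[GeneCluster]) -> list[CfeGene]:
    """Control set: loci whose isoforms all share one first exon, >= 3 exons.

    The representative transcript is the isoform with the most exons (ties by
    id); it must have at least three exons.
    """
    out = []
    for gene in genes:
        fes = {t.first_exon for t in gene.transcripts}
        if len(fes) != 1:
            continue
        rep = sorted(gene.transcripts, key=lambda t: (-t.n_exons, t.id))[0]
        if rep.n_exons < 3:
            continue
        fe = next(iter(fes))
        coding = any(
            t.cds is not None and t.first_exon.overlaps(t.cds) for t in gene.transcripts
        )
        out.append(CfeGene(gene.cluster_id, fe, rep.n_exons, coding))
    return out


@dataclass
class FunnelCounts:
    """Gene counts surviving each identification stage."""

    all_genes: int = 0
    multi_isoform: int = 0
    dalfe: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "all_genes": self.all_genes,
            "multi_isoform": self.multi_isoform,
            "dalfe": self.dalfe,
            "retained": self.retained,
        }


def call_dalfe_pairs(
    genes: Sequence[GeneCluster],
    repeats: Optional[AnnotationTrack] = None,
    probes: Optional[Sequence[GenomicInterval]] = None,
    min_exon_len: int = 61,
) -> tuple[list[DalfePair], list[DalfePair], FunnelCounts]:
    """Run identification + filters over all genes.

    Returns (kept pairs, all identified pairs with flags, funnel counts).
    """
    funnel = FunnelCounts(all_genes=len(genes))
    funnel.multi_isoform = sum(1 for g in genes if len(g) >= 2)
    if probes is not None and not isinstance(probes, AnnotationTrack):
        probes = AnnotationTrack("probes", list(probes))
    kept: list[DalfePair] = []
    identified: list[DalfePair] = []
    for gene in genes:
        pair = identify_dalfe_pair(gene)
        if pair is None:
            continue
        flagged, ok = apply_filters(pair, repeats, probes, min_exon_len)
        identified.append(flagged)
        if ok:
            kept.append(flagged)
    funnel.dalfe = len(identified)
    funnel.retained = len(kept)
    return kept, identified, funnel
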