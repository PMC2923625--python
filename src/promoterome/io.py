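"""Readers and writers for UCSC-style plain-text tables and BED tracks.

Dialects: knownGene-style transcript TSV, knownIsoforms-style cluster map,
BED3/4/6 annotation tracks and BED12 transcript models.  All readers accept
optionally gzip-compressed files.  Malformed records are skipped with counted
warnings rather than aborting, to tolerate real table dialects.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import IO, Iterator, Optional, Union

from .intervals import AnnotationTrack, GenomicInterval
from .models import TranscriptModel

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

KNOWNGENE_COLUMNS = (
    "name chrom strand txStart txEnd cdsStart cdsEnd exonCount exonStarts exonEnds"
).split()


def _open_text(path: PathLike) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _data_lines(handle: IO[str]) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        yield lineno, line.split("\t")


def _split_ints(csv: str) -> list[int]:
    return [int(x) for x in csv.rstrip(",").split(",") if x != ""]


def read_gene_models(path: PathLike, format: str = "knowngene_tsv") -> list[TranscriptModel]:
    """Read transcript models from a knownGene-style TSV or a BED12 file.

    Malformed records are skipped with a warning; the skip count is logged.
    Raises ``ValueError`` if no valid record remains and ``OSError`` if the
    file cannot be read.
    """
    if format not in ("knowngene_tsv", "bed12"):
        raise ValueError(f"unknown format: {format!r}")
    parse = _parse_knowngene if format == "knowngene_tsv" else _parse_bed12
    models: list[TranscriptModel] = []
    skipped = 0
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            try:
                models.append(parse(fields))
            except (ValueError, IndexError) as exc:
                skipped += 1
                log.warning("%s line %d skipped: %s", path, lineno, exc)
    if skipped:
        log.warning("%s: skipped %d malformed record(s)", path, skipped)
    if not models:
        raise ValueError(f"{path}: no valid transcript records")
    return models


def _parse_knowngene(fields: list[str]) -> TranscriptModel:
    if len(fields) < 10:
        raise ValueError(f"expected >= 10 columns, got {len(fields)}")
    name, chrom, strand = fields[0], fields[1], fields[2]
    tx_start, tx_end = int(fields[3]), int(fields[4])
    cds_start, cds_end = int(fields[5]), int(fields[6])
    exon_count = int(fields[7])
    starts = _split_ints(fields[8])
    ends = _split_ints(fields[9])
    if len(starts) != len(ends):
        raise ValueError(f"exonStarts count {len(starts)} != exonEnds count {len(ends)}")
    if exon_count != len(starts):
        raise ValueError(f"exonCount {exon_count} != parsed exon count {len(starts)}")
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends))
    cds = None
    if cds_end > cds_start:
        cds = GenomicInterval(chrom, cds_start, cds_end, strand)
    locus = GenomicInterval(chrom, tx_start, tx_end, strand)
    return TranscriptModel(id=name, locus=locus, exons=exons, cds=cds)


def _parse_bed12(fields: list[str]) -> TranscriptModel:
    if len(fields) < 12:
        raise ValueError(f"expected 12 columns, got {len(fields)}")
    chrom = fields[0]
    chrom_start, chrom_end = int(fields[1]), int(fields[2])
    name, strand = fields[3], fields[5]
    thick_start, thick_end = int(fields[6]), int(fields[7])
    block_count = int(fields[9])
    sizes = _split_ints(fields[10])
    offsets = _split_ints(fields[11])
    if not (block_count == len(sizes) == len(offsets)):
        raise ValueError("blockCount inconsistent with blockSizes/blockStarts")
    exons = tuple(
        GenomicInterval(chrom, chrom_start + off, chrom_start + off + size, strand)
        for off, size in zip(offsets, sizes)
    )
    cds = None
    if thick_end > thick_start:
        cds = GenomicInterval(chrom, thick_start, thick_end, strand)
    locus = GenomicInterval(chrom, chrom_start, chrom_end, strand)
    return TranscriptModel(id=name, locus=locus, exons=exons, cds=cds)


def write_gene_models(models: list[TranscriptModel], path: PathLike) -> None:
    """Write transcript models in the knownGene TSV dialect (round-trip safe)."""
    with open(path, "wt") as fh:
        for t in models:
            cds_start = t.cds.start if t.cds else t.locus.start
            cds_end = t.cds.end if t.cds else t.locus.start
            starts = ",".join(str(e.start) for e in t.exons) + ","
            ends = ",".join(str(e.end) for e in t.exons) + ","
            fh.write(
                "\t".join(
                    [
                        t.id,
                        t.chrom,
                        t.strand,
                        str(t.locus.start),
                        str(t.locus.end),
                        str(cds_start),
                        str(cds_end),
                        str(t.n_exons),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


def read_cluster_map(path: PathLike) -> dict[str, str]:
    """Read a knownIsoforms-style TSV: clusterId <tab> transcript id."""
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 2:
                log.warning("%s line %d skipped: expected 2 columns", path, lineno)
                continue
            mapping[fields[1]] = fields[0]
    return mapping


def write_cluster_map(mapping: dict[str, str], path: PathLike) -> None:
    with open(path, "wt") as fh:
        for tid in sorted(mapping):
            fh.write(f"{mapping[tid]}\t{tid}\n")


def read_track(path: PathLike, name: str = "track") -> AnnotationTrack:
    """Read a BED3+ file into an :class:`AnnotationTrack`.

    Column 4 (when present) is kept as the class label; column 6 as strand.
    Records with start >= end are skipped with a warning; an empty file yields
    an empty track.
    """
    intervals: list[GenomicInterval] = []
    labels: list[str] = []
    have_labels = False
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 3:
                log.warning("%s line %d skipped: expected >= 3 columns", path, lineno)
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                log.warning("%s line %d skipped: non-integer coordinates", path, lineno)
                continue
            if start >= end or start < 0:
                log.warning("%s line %d skipped: invalid interval %d-%d", path, lineno, start, end)
                continue
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            intervals.append(GenomicInterval(fields[0], start, end, strand))
            if len(fields) >= 4 and fields[3] != "":
                have_labels = True
                labels.append(fields[3])
            else:
                labels.append("")
    return AnnotationTrack(name, intervals, labels if have_labels else None)


def write_track(track: AnnotationTrack, path: PathLike, score: Optional[str] = None) -> None:
    """Write a track as BED (BED4 with labels, BED6 when any strand is set)."""
    stranded = any(iv.strand in ("+", "-") for iv in track.intervals)
    with open(path, "wt") as fh:
        for i, iv in enumerate(track.intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            label = track.labels[i] if track.labels is not None else track.name
            if track.labels is not None or stranded:
                fields.append(label or ".")
            if stranded:
                fields.append(score or "0")
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")
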