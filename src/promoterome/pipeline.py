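"""End-to-end orchestration: annotation -> pairs -> expression -> statistics.

Reads the input bundle, calls P1/P2 promoter pairs, builds the promoter x
tissue expression matrix, scores specificity and shared tissue preference,
overlays regulatory evidence, and writes a deterministic report bundle
(TSV tables + a machine-readable JSON summary + the serialized config).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .dalfe import (
    DalfePair,
    call_dalfe_pairs,
    classify_first_exon,
    promoter_cpg_status,
    tss_in_repeat,
)
from .evidence import (
    cage_support,
    call_tag_islands,
    distance_by_status,
    promoter_status,
    read_tag_positions,
)
from .expression import build_matrix, read_probe_table, tissue_summary
from .intervals import AnnotationTrack, GenomicInterval
from .io import read_cluster_map, read_gene_models, read_track
from .models import cluster_isoforms
from .specificity import (
    build_specificity_records,
    entropy_correlation,
    shared_preference_report,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and every tunable of the analysis, with field-standard defaults."""

    genes: str = "genes.tsv"
    isoforms: Optional[str] = "isoforms.tsv"
    probes: str = "probes.tsv"
    repeats: Optional[str] = "repeats.bed"
    cpg_islands: Optional[str] = "cpg_islands.bed"
    cage_clusters: Optional[str] = "cage_clusters.bed"
    tags: Optional[str] = "tags.bed"
    outdir: str = "promoterome_out"
    tissues: Optional[list[str]] = None
    gene_format: str = "knowngene_tsv"
    seed: int = 0
    # first-exon filters
    min_exon_len: int = 61  # keep threshold; <= 60 bp is dropped
    # replicate summarization
    replicate_fold: float = 3.5
    # entropy
    pseudocount: float = 5.0
    entropy_statistic: str = "shannon"
    entropy_low: float = 3.0
    entropy_high: float = 7.0
    # tissue preference
    preference_factor: float = 2.0
    preference_center: str = "median"
    # regulatory evidence
    island_window: int = 100
    island_min_tags: int = 3
    tss_window: int = 1000
    cage_half_window: int = 100
    cpg_window: int = 500

    def to_yaml(self, path) -> None:
        with open(path, "wt") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _pairs_to_frame(pairs: list[DalfePair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "cluster_id": p.cluster_id,
                "p1_transcript": p.p1_transcript,
                "p2_transcript": p.p2_transcript,
                "chrom": p.chrom,
                "strand": p.strand,
                "p1_tss_1based": p.p1_tss + 1,
                "p2_tss_1based": p.p2_tss + 1,
                "p1_fe_start": p.p1_first_exon.start,
                "p1_fe_end": p.p1_first_exon.end,
                "p2_fe_start": p.p2_first_exon.start,
                "p2_fe_end": p.p2_first_exon.end,
                "inter_tss_distance": p.inter_tss_distance,
                "flags": ",".join(sorted(p.flags)) or ".",
            }
        )
    return pd.DataFrame(rows).sort_values("cluster_id") if rows else pd.DataFrame()


def read_pairs_table(path) -> list[DalfePair]:
    """Reconstruct DalfePair records from a pairs TSV written by the pipeline."""
    df = pd.read_csv(path, sep="\t", dtype={"flags": str})
    pairs = []
    for _, r in df.iterrows():
        flags = frozenset() if r["flags"] == "." else frozenset(str(r["flags"]).split(","))
        pairs.append(
            DalfePair(
                cluster_id=str(r["cluster_id"]),
                p1_transcript=str(r["p1_transcript"]),
                p2_transcript=str(r["p2_transcript"]),
                chrom=str(r["chrom"]),
                strand=str(r["strand"]),
                p1_first_exon=GenomicInterval(
                    str(r["chrom"]), int(r["p1_fe_start"]), int(r["p1_fe_end"]), str(r["strand"])
                ),
                p2_first_exon=GenomicInterval(
                    str(r["chrom"]), int(r["p2_fe_start"]), int(r["p2_fe_end"]), str(r["strand"])
                ),
                p1_tss=int(r["p1_tss_1based"]) - 1,
                p2_tss=int(r["p2_tss_1based"]) - 1,
                flags=flags,
            )
        )
    return pairs


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run(config: PipelineConfig) -> dict:
    """Run all stages; returns the JSON-ready summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    transcripts = read_gene_models(config.genes, format=config.gene_format)
    cluster_map = read_cluster_map(config.isoforms) if config.isoforms else None
    genes = cluster_isoforms(transcripts, cluster_map)
    by_id = {t.id: t for t in transcripts}

    repeats = read_track(config.repeats, "repeats") if config.repeats else None
    probes = read_probe_table(config.probes)
    probe_track = AnnotationTrack(
        "probes", sorted({p.exon for p in probes})
    )

    kept, identified, funnel = call_dalfe_pairs(
        genes, repeats=repeats, probes=probe_track, min_exon_len=config.min_exon_len
    )
    log.info(
        "funnel: %d genes, %d multi-isoform, %d DAlFE, %d retained",
        funnel.all_genes,
        funnel.multi_isoform,
        funnel.dalfe,
        funnel.retained,
    )

    matrix, dropped = build_matrix(
        kept, probes, tissues=config.tissues, fold=config.replicate_fold
    )
    dropped_ids = {p.pair_id for p in dropped}
    analyzed = [p for p in kept if p.pair_id not in dropped_ids]
    funnel.retained = len(analyzed)

    records = build_specificity_records(
        matrix.values,
        pseudocount=config.pseudocount,
        statistic=config.entropy_statistic,
        low=config.entropy_low,
        high=config.entropy_high,
        factor=config.preference_factor,
        center=config.preference_center,
    )
    by_gene: dict[str, dict[str, object]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, {})[r.which] = r
    gene_ids = sorted(g for g, m in by_gene.items() if set(m) == {"P1", "P2"})
    p1_most = [by_gene[g]["P1"].most_preferred for g in gene_ids]
    p2_most = [by_gene[g]["P2"].most_preferred for g in gene_ids]
    p1_pref = [by_gene[g]["P1"].preferred_tissues for g in gene_ids]
    p2_pref = [by_gene[g]["P2"].preferred_tissues for g in gene_ids]
    table2 = shared_preference_report(
        p1_most, p2_most, matrix.tissues, p1_pref, p2_pref
    )
    ecorr = entropy_correlation(records) if len(gene_ids) >= 2 else float("nan")

    table1 = tissue_summary(matrix) if len(gene_ids) >= 2 else pd.DataFrame()

    # descriptive annotations per pair
    cpg = read_track(config.cpg_islands, "cpg") if config.cpg_islands else None
    ann_rows = []
    for p in analyzed:
        row = {"cluster_id": p.cluster_id}
        p1t, p2t = by_id.get(p.p1_transcript), by_id.get(p.p2_transcript)
        if p1t is not None:
            row["p1_first_exon_class"] = classify_first_exon(p1t)
        if p2t is not None:
            row["p2_first_exon_class"] = classify_first_exon(p2t)
        if repeats is not None:
            r1, r2 = tss_in_repeat(p, repeats)
            row["p1_tss_in_repeat"] = r1
            row["p2_tss_in_repeat"] = r2
        if cpg is not None:
            c1, c2 = promoter_cpg_status(p, cpg, window=config.cpg_window)
            row["p1_cpg"] = c1
            row["p2_cpg"] = c2
        ann_rows.append(row)

    # regulatory evidence
    evid_frame = pd.DataFrame()
    dist_status: dict[str, Optional[float]] = {}
    cage_fraction = None
    islands_all = []
    if config.tags:
        tag_map = read_tag_positions(config.tags)
        islands = {
            chrom: call_tag_islands(
                pos, window=config.island_window, min_tags=config.island_min_tags,
                chrom=chrom,
            )
            for chrom, pos in sorted(tag_map.items())
        }
        islands_all = [i for ch in sorted(islands) for i in islands[ch]]
        evidences = [
            promoter_status(p, islands.get(p.chrom, []), tss_window=config.tss_window)
            for p in analyzed
        ]
        dist_status = distance_by_status(analyzed, evidences)
        evid_frame = pd.DataFrame(
            {
                "pair_id": [e.pair_id for e in evidences],
                "status_p1": [e.status_p1 for e in evidences],
                "status_p2": [e.status_p2 for e in evidences],
                "joint": [e.joint for e in evidences],
            }
        )
    if config.cage_clusters:
        cage = read_track(config.cage_clusters, "cage")
        support, cage_fraction = cage_support(
            analyzed, cage, half_window=config.cage_half_window
        )
        if not evid_frame.empty:
            evid_frame["cage_p1"] = [
                support.get(f"{pid}:P1", False) for pid in evid_frame["pair_id"]
            ]
            evid_frame["cage_p2"] = [
                support.get(f"{pid}:P2", False) for pid in evid_frame["pair_id"]
            ]

    # ---- write the bundle -------------------------------------------------
    _write_tsv(_pairs_to_frame(identified), out / "pairs_all.tsv")
    _write_tsv(_pairs_to_frame(analyzed), out / "pairs.tsv")
    funnel_df = pd.DataFrame(
        [{"stage": k, "count": v} for k, v in funnel.as_dict().items()]
    )
    _write_tsv(funnel_df, out / "funnel.tsv")
    _write_tsv(matrix.values, out / "expression_matrix.tsv", index=True)
    if not table1.empty:
        _write_tsv(table1, out / "tissue_summary.tsv", index=True)
    spec_df = pd.DataFrame(
        {
            "promoter_id": [r.promoter_id for r in records],
            "entropy": [r.entropy for r in records],
            "entropy_class": [r.entropy_class for r in records],
            "preferred_tissues": [
                ",".join(sorted(r.preferred_tissues)) or "." for r in records
            ],
            "most_preferred": [r.most_preferred or "." for r in records],
        }
    )
    _write_tsv(spec_df, out / "specificity.tsv")
    _write_tsv(table2.reset_index(), out / "table2_shared_preference.tsv")
    if ann_rows:
        _write_tsv(pd.DataFrame(ann_rows), out / "pair_annotations.tsv")
    if not evid_frame.empty:
        _write_tsv(evid_frame, out / "evidence.tsv")
    if islands_all:
        with open(out / "islands.bed", "wt") as fh:
            for isl in islands_all:
                fh.write(
                    f"{isl.interval.chrom}\t{isl.interval.start}\t"
                    f"{isl.interval.end}\t{isl.tag_count}\n"
                )
    if dist_status:
        _write_tsv(
            pd.DataFrame(
                [
                    {"joint": k, "median_inter_tss": "" if v is None else v}
                    for k, v in sorted(dist_status.items())
                ]
            ),
            out / "distance_by_status.tsv",
        )
    # first exons of retained pairs as BED6
    with open(out / "first_exons.bed", "wt") as fh:
        for p in analyzed:
            for which in ("P1", "P2"):
                fe = p.first_exon_of(which)
                fh.write(
                    f"{fe.chrom}\t{fe.start}\t{fe.end}\t"
                    f"{p.promoter_id(which)}\t0\t{p.strand}\n"
                )

    overall = table2.loc["Total"]
    summary = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "funnel": funnel.as_dict(),
        "n_pairs_analyzed": len(analyzed),
        "excluded_above": matrix.excluded_above,
        "excluded_below": matrix.excluded_below,
        "entropy_correlation": None if pd.isna(ecorr) else ecorr,
        "total_expected_pairs": float(overall["expected_pairs"]),
        "total_observed_pairs": int(overall["observed_pairs"]),
        "median_inter_tss_by_status": dist_status,
        "cage_supported_fraction": cage_fraction,
    }
    if summary["total_expected_pairs"] > 0 and len(gene_ids):
        from .specificity import shared_preference_test

        exp = summary["total_expected_pairs"]
        if 0 < exp < len(gene_ids):
            chi2, pval = shared_preference_test(
                summary["total_observed_pairs"], exp, len(gene_ids)
            )
            summary["overall_chi2"] = chi2
            summary["overall_p_value"] = pval
    with open(out / "summary.json", "wt") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    config.to_yaml(out / "config_used.yaml")
    return summary


def make_table2(records, n_genes: int, tissues) -> pd.DataFrame:
    """Table of per-tissue preference counts and independence-model tests.

    Thin wrapper over :func:`specificity.shared_preference_report` for
    callers holding SpecificityRecord lists.
    """
    by_gene: dict[str, dict[str, object]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, {})[r.which] = r
    gene_ids = sorted(g for g, m in by_gene.items() if set(m) == {"P1", "P2"})
    if len(gene_ids) != n_genes:
        log.warning("make_table2: %d complete pairs, n_genes=%d", len(gene_ids), n_genes)
    p1 = [by_gene[g]["P1"] for g in gene_ids]
    p2 = [by_gene[g]["P2"] for g in gene_ids]
    return shared_preference_report(
        [r.most_preferred for r in p1],
        [r.most_preferred for r in p2],
        tissues,
        [r.preferred_tissues for r in p1],
        [r.preferred_tissues for r in p2],
    )
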