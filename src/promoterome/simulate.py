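"""Synthetic genomes, exon-array intensities and regulatory tracks.

Generates transcript models with planted P1/P2 alternative-promoter (DAlFE)
structure plus confounder gene types that each violate exactly one
identification or filtering rule, 11-tissue x 3-replicate log-normal probe
intensities with planted specificity classes and replicate outliers, repeat /
CpG / CAGE tracks, and ChIP tag pileups at active promoters.  Every planted
fact is recorded in a truth table so each pipeline stage can be scored
without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expression import ProbeMeasurement, write_probe_table
from .intervals import AnnotationTrack, GenomicInterval
from .io import write_cluster_map, write_gene_models, write_track
from .models import TranscriptModel

DEFAULT_TISSUES = (
    "breast",
    "cerebellum",
    "heart",
    "kidney",
    "liver",
    "muscle",
    "pancreas",
    "prostate",
    "spleen",
    "testes",
    "thyroid",
)

# default most-preferred-tissue frequency profile for the preference-label
# simulator: counts per 2,894 promoters in an 11-tissue panel (cerebellum and
# testes dominate, as in real tissue panels); the remaining mass is "no
# preference".
DEFAULT_MOST_PREFERRED_COUNTS = {
    "breast": 15,
    "cerebellum": 677,
    "heart": 49,
    "kidney": 37,
    "liver": 112,
    "muscle": 57,
    "pancreas": 45,
    "prostate": 11,
    "spleen": 189,
    "testes": 447,
    "thyroid": 32,
}
DEFAULT_MOST_PREFERRED_TOTAL = 2894

GENE_TYPES = (
    "dalfe",
    "single_isoform",
    "shared_first_exon",
    "overlapping_first_exons",
    "short_first_exon",
    "repeat_first_exon",
    "no_probe",
)
# gene types that carry a genuine (pre-filter) P1/P2 pair
PAIR_BEARING = ("dalfe", "short_first_exon", "repeat_first_exon", "no_probe")

ENTROPY_CLASSES = ("tissue_specific", "heterogeneous", "uniform")


@dataclass
class SimConfig:
    """Study conditions for the synthetic promoterome."""

    seed: int = 0
    n_genes: int = 200
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    replicates: int = 3
    chrom: str = "chrS"
    territory: int = 60_000  # bp reserved per gene
    # gene-type mixture (must sum to 1)
    mixture: dict[str, float] = field(
        default_factory=lambda: {
            "dalfe": 0.50,
            "single_isoform": 0.15,
            "shared_first_exon": 0.15,
            "overlapping_first_exons": 0.10,
            "short_first_exon": 0.04,
            "repeat_first_exon": 0.04,
            "no_probe": 0.02,
        }
    )
    # expression model
    entropy_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "tissue_specific": 0.14,
            "heterogeneous": 0.79,
            "uniform": 0.07,
        }
    )
    specific_effect: float = 20.0  # fold elevation of the preferred tissue
    baseline_log_mean: float = math.log(30.0)
    baseline_log_sd: float = 0.8
    hetero_log_sd: float = 0.6
    probe_log_sd: float = 0.15
    replicate_log_sd: float = 0.10
    probes_per_exon: tuple[int, int] = (3, 5)  # inclusive range
    # per-value replicate outlier rates (at most one outlier per triplet)
    outlier_above_rate: float = 0.056
    outlier_below_rate: float = 0.028
    # P1/P2 co-preference: probability that a tissue-specific P2 copies P1's
    # preferred tissue (0 = independence)
    preference_co_rate: float = 0.0
    fraction_utr_only: float = 0.791
    # regulatory tracks
    cpg_rate: float = 0.5
    cage_hit_rate: float = 0.9
    tags_per_active: int = 10
    tag_spread: int = 300  # tags land within +/- spread of an active TSS
    background_tag_rate: float = 1e-5  # tags per bp, genome-wide
    island_joint_probs: dict[str, float] = field(
        default_factory=lambda: {
            "YES|YES": 0.52,
            "YES|NONE": 0.172,
            "NONE|YES": 0.172,
            "NONE|NONE": 0.136,
        }
    )
    # inter-TSS distance model: two log-normal groups (short / long)
    distance_short_median: float = 700.0
    distance_long_median: float = 15_000.0
    distance_log_sd: float = 0.5

    def validate(self) -> None:
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValueError("gene-type mixture must sum to 1")
        if abs(sum(self.entropy_class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("entropy-class probabilities must sum to 1")
        for rate in (
            self.outlier_above_rate,
            self.outlier_below_rate,
            self.preference_co_rate,
            self.cage_hit_rate,
            self.cpg_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class TruthTable:
    """Planted ground truth, keyed by gene / promoter / replicate value."""

    genes: pd.DataFrame  # gene_id, gene_type, strand, joint_status, inter_tss
    promoters: pd.DataFrame  # promoter_id, entropy_class, preferred_tissue, ...
    outliers: pd.DataFrame  # probe_id, tissue, replicate, label


@dataclass
class SimResult:
    """All generated datasets plus their truth table."""

    config: SimConfig
    transcripts: list[TranscriptModel]
    cluster_map: dict[str, str]
    probes: list[ProbeMeasurement]
    repeats: AnnotationTrack
    cpg_islands: AnnotationTrack
    cage_clusters: AnnotationTrack
    tags: dict[str, np.ndarray]
    truth: TruthTable

    def write_files(self, outdir) -> dict[str, Path]:
        """Emit the file dialects the pipeline consumes; deterministic bytes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.tsv",
            "isoforms": outdir / "isoforms.tsv",
            "probes": outdir / "probes.tsv",
            "repeats": outdir / "repeats.bed",
            "cpg": outdir / "cpg_islands.bed",
            "cage": outdir / "cage_clusters.bed",
            "tags": outdir / "tags.bed",
            "truth_genes": outdir / "truth_genes.tsv",
            "truth_promoters": outdir / "truth_promoters.tsv",
            "truth_outliers": outdir / "truth_outliers.tsv",
        }
        write_gene_models(self.transcripts, paths["genes"])
        write_cluster_map(self.cluster_map, paths["isoforms"])
        write_probe_table(self.probes, paths["probes"])
        write_track(self.repeats, paths["repeats"])
        write_track(self.cpg_islands, paths["cpg"])
        write_track(self.cage_clusters, paths["cage"])
        with open(paths["tags"], "wt") as fh:
            for chrom in sorted(self.tags):
                for pos in self.tags[chrom]:
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")
        self.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
        self.truth.promoters.to_csv(paths["truth_promoters"], sep="\t", index=False)
        self.truth.outliers.to_csv(paths["truth_outliers"], sep="\t", index=False)
        return paths


class _LocalGeometry:
    """A gene's structure in transcription-direction local coordinates."""

    def __init__(self) -> None:
        self.transcripts: list[tuple[str, list[tuple[int, int]], Optional[tuple[int, int]]]] = []
        self.span = 0
        self.p2_offset: Optional[int] = None  # local TSS of P2 (pair-bearing types)
        self.repeat_local: list[tuple[int, int, str]] = []


def _draw_geometry(
    gene_type: str, rng: np.random.Generator, cfg: SimConfig, joint: str
) -> _LocalGeometry:
    geo = _LocalGeometry()
    l1 = int(rng.integers(120, 301))
    if gene_type in PAIR_BEARING or gene_type == "overlapping_first_exons":
        l2 = (
            int(rng.integers(20, 61))
            if gene_type == "short_first_exon"
            else int(rng.integers(120, 301))
        )
        if gene_type == "overlapping_first_exons":
            d = max(10, l1 - 60)
        else:
            # co-modified pairs are biased toward the short-distance group
            p_short = {"YES|YES": 0.8, "NONE|NONE": 0.2}.get(joint, 0.35)
            med = (
                cfg.distance_short_median
                if rng.random() < p_short
                else cfg.distance_long_median
            )
            d = int(rng.lognormal(math.log(med), cfg.distance_log_sd))
            d = int(np.clip(d, l1 + 100, cfg.territory - 4000))
        s1 = max(d + l2, l1) + 500
        s2 = s1 + 150 + 300
        exons1 = [(0, l1), (s1, s1 + 150), (s2, s2 + 150)]
        exons2 = [(d, d + l2), (s1, s1 + 150), (s2, s2 + 150)]
        cds_shared = (s1 + 20, s2 + 130)
        geo.transcripts.append(("a", exons1, cds_shared))
        geo.transcripts.append(("b", exons2, cds_shared))
        geo.span = s2 + 150 + 200
        geo.p2_offset = d
        if gene_type == "repeat_first_exon":
            geo.repeat_local.append((d + 10, d + 40, "AluY"))
    elif gene_type == "single_isoform":
        s1 = l1 + 2000
        s2 = s1 + 150 + 300
        geo.transcripts.append(
            ("a", [(0, l1), (s1, s1 + 150), (s2, s2 + 150)], (s1 + 20, s2 + 130))
        )
        geo.span = s2 + 150 + 200
    elif gene_type == "shared_first_exon":
        s1 = l1 + 2000
        s2 = s1 + 150 + 300
        s3 = s2 + 150 + 300
        cds = (s1 + 20, s3 + 130)
        geo.transcripts.append(
            ("a", [(0, l1), (s1, s1 + 150), (s2, s2 + 150), (s3, s3 + 150)], cds)
        )
        geo.transcripts.append(("b", [(0, l1), (s1, s1 + 150), (s3, s3 + 150)], cds))
        geo.span = s3 + 150 + 200
    else:
        raise ValueError(f"unknown gene type: {gene_type}")
    return geo


def _to_genomic(
    local: tuple[int, int], gstart: int, gend: int, strand: str
) -> tuple[int, int]:
    a, b = local
    if strand == "+":
        return gstart + a, gstart + b
    return gend - b, gend - a


def _tissue_means(
    entropy_class: str,
    preferred: Optional[str],
    rng: np.random.Generator,
    cfg: SimConfig,
) -> dict[str, float]:
    base = float(rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd))
    means = {}
    for t in cfg.tissues:
        if entropy_class == "uniform":
            means[t] = base
        elif entropy_class == "tissue_specific":
            means[t] = base * cfg.specific_effect if t == preferred else base
        else:
            means[t] = base * float(rng.lognormal(0.0, cfg.hetero_log_sd))
    return means


def plant_expression(
    probe_specs: Sequence[tuple[str, GenomicInterval, dict[str, float]]],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[ProbeMeasurement], pd.DataFrame]:
    """Draw replicate intensities for probes with given per-tissue means.

    Each (probe, tissue) triplet receives at most one planted outlier, drawn
    so that the per-value outlier rates match the configured rates; outliers
    multiply (or divide) one replicate by a factor of 5-10x, guaranteeing
    exclusion under the 3.5-fold rule while the two clean values anchor the
    median.
    """
    p_above = cfg.replicates * cfg.outlier_above_rate
    p_below = cfg.replicates * cfg.outlier_below_rate
    if p_above + p_below > 1.0:
        raise ValueError("outlier rates too large for the replicate count")
    probes: list[ProbeMeasurement] = []
    truth_rows = []
    for probe_id, exon, means in probe_specs:
        probe_mult = float(rng.lognormal(0.0, cfg.probe_log_sd))
        for tissue in cfg.tissues:
            mu = means[tissue] * probe_mult
            values = mu * rng.lognormal(0.0, cfg.replicate_log_sd, cfg.replicates)
            u = rng.random()
            labels = ["kept"] * cfg.replicates
            if u < p_above:
                i = int(rng.integers(cfg.replicates))
                values[i] *= float(rng.uniform(5.0, 10.0))
                labels[i] = "above"
            elif u < p_above + p_below:
                i = int(rng.integers(cfg.replicates))
                values[i] /= float(rng.uniform(5.0, 10.0))
                labels[i] = "below"
            for r in range(cfg.replicates):
                probes.append(
                    ProbeMeasurement(
                        probe_id=probe_id,
                        exon=exon,
                        tissue=tissue,
                        replicate=r + 1,
                        intensity=float(values[r]),
                    )
                )
                truth_rows.append((probe_id, tissue, r + 1, labels[r]))
    outliers = pd.DataFrame(
        truth_rows, columns=["probe_id", "tissue", "replicate", "label"]
    )
    return probes, outliers


def generate(config: SimConfig) -> SimResult:
    """Generate the full synthetic bundle; deterministic under config.seed."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chrom = cfg.chrom

    transcripts: list[TranscriptModel] = []
    cluster_map: dict[str, str] = {}
    repeat_ivs: list[GenomicInterval] = []
    repeat_labels: list[str] = []
    cpg_ivs: list[GenomicInterval] = []
    cage_ivs: list[GenomicInterval] = []
    tag_positions: list[int] = []
    probe_specs: list[tuple[str, GenomicInterval, dict[str, float]]] = []
    gene_rows = []
    promoter_rows = []

    type_names = sorted(cfg.mixture)
    type_probs = np.array([cfg.mixture[t] for t in type_names])
    class_names = sorted(cfg.entropy_class_probs)
    class_probs = np.array([cfg.entropy_class_probs[c] for c in class_names])
    joint_names = sorted(cfg.island_joint_probs)
    joint_probs = np.array([cfg.island_joint_probs[j] for j in joint_names])

    probe_counter = 0
    for g in range(cfg.n_genes):
        gene_id = f"g{g:05d}"
        gene_type = type_names[int(rng.choice(len(type_names), p=type_probs))]
        strand = "+" if rng.random() < 0.5 else "-"
        joint = joint_names[int(rng.choice(len(joint_names), p=joint_probs))]
        geo = _draw_geometry(gene_type, rng, cfg, joint)
        gstart = 1000 + g * cfg.territory
        gend = gstart + geo.span

        # materialize transcripts in genomic coordinates
        models_here = []
        for suffix, local_exons, local_cds in geo.transcripts:
            g_exons = sorted(
                _to_genomic(e, gstart, gend, strand) for e in local_exons
            )
            exons = tuple(
                GenomicInterval(chrom, a, b, strand) for a, b in g_exons
            )
            utr_only = rng.random() < cfg.fraction_utr_only
            if local_cds is not None:
                if not utr_only:
                    # extend the CDS into the first exon
                    first = local_exons[0]
                    local_cds = (first[0] + max(1, (first[1] - first[0]) // 2), local_cds[1])
                a, b = _to_genomic(local_cds, gstart, gend, strand)
                cds = GenomicInterval(chrom, a, b, strand)
            else:
                cds = None
            locus = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
            tid = f"{gene_id}.{suffix}"
            model = TranscriptModel(id=tid, locus=locus, exons=exons, cds=cds)
            transcripts.append(model)
            cluster_map[tid] = gene_id
            models_here.append(model)

        for a, b, cls in geo.repeat_local:
            ga, gb = _to_genomic((a, b), gstart, gend, strand)
            repeat_ivs.append(GenomicInterval(chrom, ga, gb))
            repeat_labels.append(cls)
        # background repeat in the shared-exon gap, away from all exons
        if gene_type in PAIR_BEARING and rng.random() < 0.4:
            p2_end_local = geo.p2_offset + geo.transcripts[1][1][0][1] - geo.transcripts[1][1][0][0]
            ga, gb = _to_genomic((p2_end_local + 100, p2_end_local + 160), gstart, gend, strand)
            cls = str(rng.choice(["L1MA4", "MIR", "Simple_repeat", "Low_complexity"]))
            repeat_ivs.append(GenomicInterval(chrom, ga, gb))
            repeat_labels.append(cls)

        # promoter-level planting: only pair-bearing genes are quantified
        inter_tss = None
        if gene_type in PAIR_BEARING or gene_type == "overlapping_first_exons":
            inter_tss = geo.p2_offset
        if gene_type in PAIR_BEARING:
            p1_model, p2_model = models_here[0], models_here[1]
            classes = {}
            preferred = {}
            for which, model in (("P1", p1_model), ("P2", p2_model)):
                eclass = class_names[int(rng.choice(len(class_names), p=class_probs))]
                classes[which] = eclass
            for which in ("P1", "P2"):
                if classes[which] != "tissue_specific":
                    preferred[which] = None
                    continue
                if (
                    which == "P2"
                    and classes["P1"] == "tissue_specific"
                    and preferred.get("P1") is not None
                    and rng.random() < cfg.preference_co_rate
                ):
                    preferred["P2"] = preferred["P1"]
                else:
                    preferred[which] = str(rng.choice(cfg.tissues))
            active = {"P1": joint.split("|")[0] == "YES", "P2": joint.split("|")[1] == "YES"}
            for which, model in (("P1", p1_model), ("P2", p2_model)):
                tss = model.tss
                fe = model.first_exon
                means = _tissue_means(classes[which], preferred[which], rng, cfg)
                # probes on the first exon (withheld for P2 of no_probe genes)
                emit_probes = not (gene_type == "no_probe" and which == "P2")
                if emit_probes:
                    n_probes = int(
                        rng.integers(cfg.probes_per_exon[0], cfg.probes_per_exon[1] + 1)
                    )
                    plen = min(25, fe.length)
                    for _ in range(n_probes):
                        start = int(rng.integers(fe.start, fe.end - plen + 1))
                        probe_counter += 1
                        probe_specs.append(
                            (
                                f"pr{probe_counter:06d}",
                                GenomicInterval(chrom, start, start + plen, strand),
                                means,
                            )
                        )
                # CpG island
                if rng.random() < cfg.cpg_rate:
                    cpg_ivs.append(
                        GenomicInterval(chrom, max(0, tss - 200), tss + 200)
                    )
                # CAGE cluster at the TSS
                cage_hit = rng.random() < cfg.cage_hit_rate
                if cage_hit:
                    cage_ivs.append(
                        GenomicInterval(chrom, max(0, tss - 20), tss + 21, strand)
                    )
                # ChIP tags at active promoters
                if active[which] and cfg.tags_per_active > 0:
                    tag_positions.extend(
                        int(p)
                        for p in rng.integers(
                            max(0, tss - cfg.tag_spread),
                            tss + cfg.tag_spread,
                            cfg.tags_per_active,
                        )
                    )
                promoter_rows.append(
                    {
                        "promoter_id": f"{gene_id}:{which}",
                        "gene_id": gene_id,
                        "which": which,
                        "tss": tss,
                        "entropy_class": classes[which],
                        "preferred_tissue": preferred[which] or "",
                        "active": active[which],
                        "cage_supported": cage_hit,
                    }
                )
        else:
            # non-pair genes still get probes with an unplanted profile so
            # that probe coverage resembles a real array design
            model = models_here[0]
            fe = model.first_exon
            means = _tissue_means("heterogeneous", None, rng, cfg)
            plen = min(25, fe.length)
            for _ in range(3):
                start = int(rng.integers(fe.start, fe.end - plen + 1))
                probe_counter += 1
                probe_specs.append(
                    (
                        f"pr{probe_counter:06d}",
                        GenomicInterval(chrom, start, start + plen, strand),
                        means,
                    )
                )

        gene_rows.append(
            {
                "gene_id": gene_id,
                "gene_type": gene_type,
                "strand": strand,
                "joint_status": joint if gene_type in PAIR_BEARING else "",
                "inter_tss_distance": inter_tss if inter_tss is not None else -1,
            }
        )

    # genome-wide background tags
    genome_span = 1000 + cfg.n_genes * cfg.territory
    n_bg = int(rng.poisson(cfg.background_tag_rate * genome_span))
    if n_bg:
        tag_positions.extend(int(p) for p in rng.integers(0, genome_span, n_bg))

    probes, outliers = plant_expression(probe_specs, cfg, rng)

    truth = TruthTable(
        genes=pd.DataFrame(gene_rows),
        promoters=pd.DataFrame(
            promoter_rows,
            columns=[
                "promoter_id",
                "gene_id",
                "which",
                "tss",
                "entropy_class",
                "preferred_tissue",
                "active",
                "cage_supported",
            ],
        ),
        outliers=outliers,
    )
    return SimResult(
        config=cfg,
        transcripts=transcripts,
        cluster_map=cluster_map,
        probes=probes,
        repeats=AnnotationTrack("repeats", repeat_ivs, repeat_labels),
        cpg_islands=AnnotationTrack("cpg", cpg_ivs),
        cage_clusters=AnnotationTrack("cage", cage_ivs),
        tags={chrom: np.sort(np.asarray(tag_positions, dtype=np.int64))},
        truth=truth,
    )


def default_tissue_preference_probs(
    counts: Optional[dict[str, int]] = None, total: Optional[int] = None
) -> dict[str, float]:
    """Per-promoter most-preferred-tissue probabilities (rest = none)."""
    counts = counts or DEFAULT_MOST_PREFERRED_COUNTS
    total = total or DEFAULT_MOST_PREFERRED_TOTAL
    return {t: c / total for t, c in counts.items()}


def co_rate_for_doubling(probs: dict[str, float]) -> float:
    """Copy rate rho that doubles the expected shared-preference pair total.

    Under copying, P(both = t) = q_t (rho + (1 - rho) q_t); solving
    sum_t = 2 sum_t q_t^2 gives rho = S2 / (S1 - S2) with S1 = sum q_t,
    S2 = sum q_t^2.
    """
    q = np.asarray(list(probs.values()))
    s1, s2 = float(q.sum()), float((q * q).sum())
    return s2 / (s1 - s2)


def simulate_preference_labels(
    n_genes: int,
    probs: Optional[dict[str, float]] = None,
    co_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> tuple[list[Optional[str]], list[Optional[str]]]:
    """Draw paired most-preferred-tissue labels for G genes.

    P1 labels are drawn from *probs* (missing mass = no preference); P2
    copies P1's label with probability *co_rate* when P1 has one, otherwise
    draws independently.  co_rate = 0 is the independence null.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    probs = probs or default_tissue_preference_probs()
    tissues = sorted(probs)
    p = np.array([probs[t] for t in tissues])
    p_none = 1.0 - p.sum()
    if p_none < -1e-9:
        raise ValueError("preference probabilities exceed 1")
    choices: list[Optional[str]] = list(tissues) + [None]
    full = np.append(p, max(p_none, 0.0))
    full = full / full.sum()

    idx1 = rng.choice(len(choices), size=n_genes, p=full)
    copy = rng.random(n_genes) < co_rate
    idx2 = rng.choice(len(choices), size=n_genes, p=full)
    p1 = [choices[i] for i in idx1]
    p2 = [
        choices[i1] if (c and choices[i1] is not None) else choices[i2]
        for i1, c, i2 in zip(idx1, copy, idx2)
    ]
    return p1, p2
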