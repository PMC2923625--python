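"""Exon-probe expression summarization for promoter pairs.

Probe intensities (normalized exon-array signals, one value per tissue and
replicate) are mapped to first exons by genomic overlap, replicates are
summarized by a median that discards values differing more than 3.5-fold from
the replicate median, and multiple probes per exon are combined by their
median.  The result is a promoter x tissue expression matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dalfe import DalfePair
from .intervals import AnnotationTrack, GenomicInterval
from .io import PathLike, _data_lines, _open_text

log = logging.getLogger(__name__)

KEPT, ABOVE, BELOW = "kept", "above", "below"


@dataclass(frozen=True)
class ProbeMeasurement:
    """One probe's intensity in one tissue replicate."""

    probe_id: str
    exon: GenomicInterval
    tissue: str
    replicate: int
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"{self.probe_id}: negative intensity {self.intensity}")


@dataclass
class ExpressionMatrix:
    """Promoter x tissue summarized intensities with exclusion provenance."""

    values: pd.DataFrame  # rows: promoter ids, columns: tissue names
    excluded_above: float
    excluded_below: float
    replicate_labels: Optional[pd.DataFrame] = None  # probe/tissue/replicate/label

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def promoters(self) -> list[str]:
        return list(self.values.index)

    def pair_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Split into aligned P1 and P2 frames indexed by gene."""
        p1 = self.values[self.values.index.str.endswith(":P1")].copy()
        p2 = self.values[self.values.index.str.endswith(":P2")].copy()
        p1.index = p1.index.str.replace(":P1", "", regex=False)
        p2.index = p2.index.str.replace(":P2", "", regex=False)
        common = p1.index.intersection(p2.index)
        return p1.loc[common], p2.loc[common]


def summarize_replicates(
    values: Sequence[float], fold: float = 3.5
) -> tuple[float, list[str]]:
    """Median of replicates, discarding values > *fold* from the median.

    The reference median is computed once over all replicates; a value v is
    labelled 'above' when v > fold*m, 'below' when v < m/fold (for m > 0), and
    the summary is the median of the kept values.  With m = 0 all zero values
    are kept and the summary is 0 (positive values then count as 'above').
    """
    values = list(values)
    if not values:
        raise ValueError("empty replicate list")
    if any(v < 0 for v in values):
        raise ValueError("negative intensity")
    m = median(values)
    labels = []
    for v in values:
        if m == 0:
            labels.append(KEPT if v == 0 else ABOVE)
        elif v > fold * m:
            labels.append(ABOVE)
        elif v < m / fold:
            labels.append(BELOW)
        else:
            labels.append(KEPT)
    kept = [v for v, l in zip(values, labels) if l == KEPT]
    if not kept:  # only possible when m == 0 and all values positive; unreachable
        kept = values
    return float(median(kept)), labels


def map_probes(
    pairs: Sequence[DalfePair], probes: Sequence[ProbeMeasurement]
) -> dict[str, list[str]]:
    """Assign probes to promoters by >= 1 bp overlap with the first exon.

    Returns promoter id -> sorted probe ids; promoters without probes map to
    an empty list.
    """
    unique: dict[str, GenomicInterval] = {}
    for p in probes:
        unique.setdefault(p.probe_id, p.exon)
    track = AnnotationTrack(
        "probes", list(unique.values()), labels=list(unique.keys())
    )
    assignment: dict[str, list[str]] = {}
    for pair in pairs:
        for which in ("P1", "P2"):
            fe = pair.first_exon_of(which)
            hits = sorted({lab for _, lab in track.overlapping(fe)})
            assignment[pair.promoter_id(which)] = hits
    return assignment


def build_matrix(
    pairs: Sequence[DalfePair],
    probes: Sequence[ProbeMeasurement],
    tissues: Optional[Sequence[str]] = None,
    fold: float = 3.5,
) -> tuple[ExpressionMatrix, list[DalfePair]]:
    """Assemble the promoter x tissue matrix.

    Pairs where either promoter lacks probes are dropped (flagged no_probe)
    and returned separately.  Raises ``ValueError`` when an assigned probe has
    no replicate at all for some tissue in the panel.
    """
    if tissues is None:
        tissues = sorted({p.tissue for p in probes})
    tissues = list(tissues)
    by_probe: dict[str, dict[str, list[float]]] = {}
    for p in probes:
        by_probe.setdefault(p.probe_id, {}).setdefault(p.tissue, []).append(p.intensity)

    assignment = map_probes(pairs, probes)
    kept_pairs: list[DalfePair] = []
    dropped: list[DalfePair] = []
    for pair in pairs:
        if assignment[pair.promoter_id("P1")] and assignment[pair.promoter_id("P2")]:
            kept_pairs.append(pair)
        else:
            dropped.append(pair.with_flags("no_probe"))
            log.info("pair %s dropped: no probe on a first exon", pair.pair_id)

    # summarize each needed probe x tissue once
    needed = sorted(
        {pid for pair in kept_pairs for w in ("P1", "P2")
         for pid in assignment[pair.promoter_id(w)]}
    )
    summaries: dict[tuple[str, str], float] = {}
    label_rows = []
    n_above = n_below = n_total = 0
    for pid in needed:
        for tissue in tissues:
            reps = by_probe.get(pid, {}).get(tissue)
            if not reps:
                raise ValueError(f"probe {pid}: no replicate for tissue {tissue}")
            value, labels = summarize_replicates(reps, fold=fold)
            summaries[(pid, tissue)] = value
            for r, lab in enumerate(labels, start=1):
                label_rows.append((pid, tissue, r, lab))
            n_total += len(labels)
            n_above += labels.count(ABOVE)
            n_below += labels.count(BELOW)

    rows = {}
    for pair in kept_pairs:
        for which in ("P1", "P2"):
            prom = pair.promoter_id(which)
            pids = assignment[prom]
            rows[prom] = [
                float(median([summaries[(pid, t)] for pid in pids])) for t in tissues
            ]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
    values = values.sort_index()
    matrix = ExpressionMatrix(
        values=values,
        excluded_above=n_above / n_total if n_total else 0.0,
        excluded_below=n_below / n_total if n_total else 0.0,
        replicate_labels=pd.DataFrame(
            label_rows, columns=["probe_id", "tissue", "replicate", "label"]
        ),
    )
    return matrix, dropped


def tissue_summary(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-tissue mean/median for P1 and P2 plus the paired Pearson r.

    Correlations are computed on untransformed summarized intensities across
    gene pairs; a zero-variance vector yields a missing correlation.
    """
    p1, p2 = matrix.pair_frames()
    if len(p1) < 2:
        raise ValueError("need >= 2 pairs for per-tissue correlation")
    rows = []
    for t in matrix.tissues:
        x, y = p1[t].to_numpy(float), p2[t].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(x, y).statistic)
        rows.append(
            {
                "tissue": t,
                "p1_mean": float(np.mean(x)),
                "p1_median": float(np.median(x)),
                "p2_mean": float(np.mean(y)),
                "p2_median": float(np.median(y)),
                "pearson_r": r,
            }
        )
    return pd.DataFrame(rows).set_index("tissue")


def read_probe_table(path: PathLike) -> list[ProbeMeasurement]:
    """Read a probe TSV: probe_id chrom start end strand tissue replicate intensity."""
    out: list[ProbeMeasurement] = []
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            if fields[0] == "probe_id":  # header
                continue
            if len(fields) < 8:
                log.warning("%s line %d skipped: expected 8 columns", path, lineno)
                continue
            exon = GenomicInterval(fields[1], int(fields[2]), int(fields[3]), fields[4])
            out.append(
                ProbeMeasurement(
                    probe_id=fields[0],
                    exon=exon,
                    tissue=fields[5],
                    replicate=int(fields[6]),
                    intensity=float(fields[7]),
                )
            )
    return out


def write_probe_table(probes: Sequence[ProbeMeasurement], path: PathLike) -> None:
    with open(path, "wt") as fh:
        fh.write("probe_id\tchrom\tstart\tend\tstrand\ttissue\treplicate\tintensity\n")
        for p in probes:
            fh.write(
                f"{p.probe_id}\t{p.exon.chrom}\t{p.exon.start}\t{p.exon.end}\t"
                f"{p.exon.strand}\t{p.tissue}\t{p.replicate}\t{p.intensity:.6g}\n"
            )
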