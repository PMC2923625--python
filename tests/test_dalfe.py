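"""P1/P2 pair identification, filters and first-exon descriptive features."""

import numpy as np
import pytest

from promoterome.dalfe import (
    apply_filters,
    build_cfe_controls,
    classify_first_exon,
    first_exon,
    identify_dalfe_pair,
    promoter_cpg_status,
    repeat_association_stats,
    tss_in_repeat,
)
from promoterome.intervals import AnnotationTrack, GenomicInterval
from promoterome.models import GeneCluster

from conftest import oracle_dalfe_pair, random_cluster, tx


def iv(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


@pytest.mark.parametrize(
    "strand,expected",
    [("+", (0, 200)), ("-", (1000, 1200))],
)
def test_first_exon_is_strand_aware(strand, expected):
    t = tx("t", [(0, 200), (1000, 1200)], strand=strand)
    fe = first_exon(t)
    assert (fe.start, fe.end) == expected


def test_single_exon_transcript_first_exon():
    t = tx("t", [(100, 400)], strand="-")
    assert (first_exon(t).start, first_exon(t).end) == (100, 400)


def test_single_isoform_gene_yields_no_pair():
    gene = GeneCluster("g", [tx("only", [(0, 200), (1000, 1200)])])
    assert identify_dalfe_pair(gene) is None


def test_intronic_downstream_first_exon_forms_pair():
    t1 = tx("T1", [(0, 200), (1000, 1200), (2000, 2300)])
    t2 = tx("T2", [(500, 700), (2000, 2300)])
    pair = identify_dalfe_pair(GeneCluster("g", [t1, t2]))
    assert pair is not None
    assert (pair.p1_transcript, pair.p2_transcript) == ("T1", "T2")
    assert (pair.p1_tss, pair.p2_tss) == (0, 500)
    assert pair.inter_tss_distance == 500
    assert (pair.p2_first_exon.start, pair.p2_first_exon.end) == (500, 700)


def test_overlapping_first_exons_disqualify():
    t1 = tx("T1", [(0, 200), (1000, 1200), (2000, 2300)])
    t2 = tx("T2", [(150, 700), (2000, 2300)])
    assert identify_dalfe_pair(GeneCluster("g", [t1, t2])) is None


def test_minus_strand_mirror_keeps_p1_upstream():
    # reflection of the qualifying plus-strand example around x -> 3000 - x
    def mirror(exons):
        return sorted((3000 - b, 3000 - a) for a, b in exons)

    t1 = tx("T1", mirror([(0, 200), (1000, 1200), (2000, 2300)]), strand="-")
    t2 = tx("T2", mirror([(500, 700), (2000, 2300)]), strand="-")
    pair = identify_dalfe_pair(GeneCluster("g", [t1, t2]))
    assert pair is not None
    assert (pair.p1_transcript, pair.p2_transcript) == ("T1", "T2")
    assert pair.p1_tss == 2999 and pair.p2_tss == 2499
    assert pair.inter_tss_distance == 500


def test_pair_caller_matches_bruteforce_oracle(rng):
    """Scan-ordered caller equals exhaustive pair enumeration on random clusters."""
    n_with_pair = 0
    for _ in range(400):
        cluster = random_cluster(rng)
        pair = identify_dalfe_pair(cluster)
        expected = oracle_dalfe_pair(cluster)
        got = None if pair is None else (pair.p1_transcript, pair.p2_transcript)
        assert got == expected
        n_with_pair += got is not None
    assert n_with_pair > 10  # the comparison actually exercised positives


def test_strand_reflection_symmetry(rng):
    """Reflecting coordinates and flipping strand preserves P1/P2 roles."""
    for _ in range(100):
        cluster = random_cluster(rng)
        span = max(t.locus.end for t in cluster.transcripts) + 10
        flip = {"+": "-", "-": "+"}[cluster.strand]
        mirrored = GeneCluster(
            "g",
            [
                tx(
                    t.id,
                    [(span - e.end, span - e.start) for e in t.exons],
                    strand=flip,
                )
                for t in cluster.transcripts
            ],
        )
        a = identify_dalfe_pair(cluster)
        b = identify_dalfe_pair(mirrored)
        if a is None:
            assert b is None
        else:
            assert b is not None
            assert (a.p1_transcript, a.p2_transcript) == (b.p1_transcript, b.p2_transcript)
            assert a.inter_tss_distance == b.inter_tss_distance


def _pair(l1=(0, 200), l2=(500, 700)):
    t1 = tx("T1", [l1, (1000, 1200), (2000, 2300)])
    t2 = tx("T2", [l2, (2000, 2300)])
    return identify_dalfe_pair(GeneCluster("g", [t1, t2]))


def test_short_first_exon_filter_drops_at_60bp():
    pair = _pair(l2=(500, 560))  # 60 bp exactly -> too short
    flagged, keep = apply_filters(pair)
    assert not keep and "short_first_exon" in flagged.flags
    flagged61, keep61 = apply_filters(_pair(l2=(500, 561)))
    assert keep61 and not flagged61.flags


def test_repeat_overlap_filter_one_bp_rule():
    pair = _pair()
    repeats = AnnotationTrack("repeats", [iv(550, 560)])
    flagged, keep = apply_filters(pair, repeats=repeats)
    assert not keep and "repeat_in_first_exon" in flagged.flags
    # repeat outside both first exons
    _, keep2 = apply_filters(pair, repeats=AnnotationTrack("r", [iv(900, 950)]))
    assert keep2


def test_missing_probe_flags_pair():
    pair = _pair()
    probes = [iv(10, 35)]  # only P1's exon covered
    flagged, keep = apply_filters(pair, probes=probes)
    assert not keep and "no_probe" in flagged.flags
    _, keep2 = apply_filters(pair, probes=[iv(10, 35), iv(600, 625)])
    assert keep2


@pytest.mark.parametrize(
    "cds,expected",
    [
        ((150, 2100), "contains_coding"),
        ((1000, 2100), "utr_only"),
        (None, "utr_only"),
    ],
)
def test_first_exon_coding_classification(cds, expected):
    t = tx("T", [(0, 200), (1000, 1200), (2000, 2300)], cds=cds)
    assert classify_first_exon(t) == expected


def test_tss_in_repeat_half_open_boundary():
    t1 = tx("T1", [(100, 300), (1000, 1200), (2000, 2300)])
    t2 = tx("T2", [(500, 700), (2000, 2300)])
    pair = identify_dalfe_pair(GeneCluster("g", [t1, t2]))
    assert tss_in_repeat(pair, AnnotationTrack("r", [iv(50, 150)])) == (True, False)
    # TSS at 100; repeat ending exactly at 100 excludes it (half-open)
    assert tss_in_repeat(pair, AnnotationTrack("r", [iv(50, 100)])) == (False, False)
    assert tss_in_repeat(pair, AnnotationTrack("r", [])) == (False, False)


def test_promoter_cpg_window_is_half_open():
    t1 = tx("T1", [(1000, 1200), (2000, 2300), (3000, 3300)])
    t2 = tx("T2", [(1500, 1700), (3000, 3300)])
    pair = identify_dalfe_pair(GeneCluster("g", [t1, t2]))
    # P1 TSS = 1000, window [500, 1500)
    assert promoter_cpg_status(pair, AnnotationTrack("cpg", [iv(900, 1400)]))[0]
    assert not promoter_cpg_status(pair, AnnotationTrack("cpg", [iv(2000, 2200)]))[0]
    assert not promoter_cpg_status(pair, AnnotationTrack("cpg", [iv(1500, 1600)]))[0]


def test_repeat_association_fold_and_exclusions():
    dalfe = [iv(i * 1000, i * 1000 + 100) for i in range(100)]
    cfe = [iv(500_000 + i * 1000, 500_000 + i * 1000 + 100) for i in range(100)]
    hits = [iv(i * 1000 + 10, i * 1000 + 40) for i in range(10)]  # 10 DAlFE hits
    hits += [iv(500_000 + i * 1000 + 10, 500_000 + i * 1000 + 40) for i in range(5)]
    track = AnnotationTrack("r", hits, labels=["AluY"] * 15)
    res = repeat_association_stats(dalfe, cfe, track)
    assert res.table == ((10, 90), (5, 95))
    assert res.fold == pytest.approx(2.0)
    # identical proportions -> fold 1, symmetric table, p = 1
    res2 = repeat_association_stats(dalfe[:50], cfe[:50], AnnotationTrack("r", [], []))
    assert res2.fold == pytest.approx(1.0)
    assert res2.p_value == pytest.approx(1.0)
    # everything in excluded classes counts as zero overlap
    excluded = AnnotationTrack("r", hits, labels=["Simple_repeat"] * 15)
    res3 = repeat_association_stats(dalfe, cfe, excluded)
    assert res3.table == ((0, 100), (0, 100))


def test_cfe_control_set_rules():
    shared = [
        tx("A", [(0, 200), (1000, 1200), (2000, 2300), (3000, 3100)]),
        tx("B", [(0, 200), (1000, 1200), (3000, 3100)]),
    ]
    different = [tx("C", [(0, 200), (2000, 2300)]), tx("D", [(500, 700), (2000, 2300)])]
    twoexon = [tx("E", [(0, 200), (2000, 2300)])]
    out = build_cfe_controls(
        [
            GeneCluster("g1", shared),
            GeneCluster("g2", different),
            GeneCluster("g3", twoexon),
        ]
    )
    assert [c.cluster_id for c in out] == ["g1"]
    assert out[0].n_exons == 4
    assert (out[0].shared_first_exon.start, out[0].shared_first_exon.end) == (0, 200)
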