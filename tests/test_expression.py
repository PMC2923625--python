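"""Replicate summarization and the promoter x tissue expression matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promoterome.dalfe import identify_dalfe_pair
from promoterome.expression import (
    ProbeMeasurement,
    build_matrix,
    map_probes,
    summarize_replicates,
    tissue_summary,
)
from promoterome.intervals import GenomicInterval
from promoterome.models import GeneCluster

from conftest import tx


@pytest.mark.parametrize(
    "values,expected,labels",
    [
        ([10, 10, 10], 10, ["kept", "kept", "kept"]),
        ([10, 12, 100], 11, ["kept", "kept", "above"]),  # 100 > 3.5 * 12
        ([0.5, 12, 13], 12.5, ["below", "kept", "kept"]),  # 0.5 < 12 / 3.5
        ([0, 0, 0], 0, ["kept", "kept", "kept"]),
    ],
)
def test_replicate_summarization_rule(values, expected, labels):
    value, got_labels = summarize_replicates(values)
    assert value == pytest.approx(expected)
    assert got_labels == labels


def test_boundary_value_at_exactly_fold_is_kept():
    # v == 3.5 * m is not "exceeding" the fold difference
    value, labels = summarize_replicates([10, 10, 35])
    assert labels == ["kept", "kept", "kept"]
    assert value == 10


def test_empty_replicates_error():
    with pytest.raises(ValueError):
        summarize_replicates([])


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(
        st.integers(min_value=0, max_value=10**6).map(float), min_size=1, max_size=6
    ),
    st.integers(min_value=1, max_value=100).map(float),
)
def test_summarizer_permutation_and_scale_properties(values, c):
    base, _ = summarize_replicates(values)
    perm, _ = summarize_replicates(values[::-1])
    assert perm == base
    scaled, _ = summarize_replicates([c * v for v in values])
    assert scaled == pytest.approx(c * base, rel=1e-9)
    assert min(values) <= base <= max(values)


def _probe(pid, start, end, tissue, rep, value, chrom="chr1"):
    return ProbeMeasurement(
        probe_id=pid,
        exon=GenomicInterval(chrom, start, end, "+"),
        tissue=tissue,
        replicate=rep,
        intensity=value,
    )


def _demo_pair():
    t1 = tx("T1", [(0, 200), (1000, 1200), (2000, 2300)])
    t2 = tx("T2", [(500, 700), (2000, 2300)])
    return identify_dalfe_pair(GeneCluster("g", [t1, t2]))


def test_probe_assignment_by_first_exon_overlap():
    pair = _demo_pair()
    probes = [
        _probe("a", 0, 120, "liver", 1, 5.0),
        _probe("b", 300, 400, "liver", 1, 5.0),  # intronic, unassigned
        _probe("c", 690, 720, "liver", 1, 5.0),  # 10 bp overlap with P2 exon
    ]
    assignment = map_probes([pair], probes)
    assert assignment["g:P1"] == ["a"]
    assert assignment["g:P2"] == ["c"]


def test_pair_without_p2_probes_is_dropped():
    pair = _demo_pair()
    probes = [_probe("a", 0, 120, t, r, 5.0) for t in ("liver", "heart") for r in (1, 2, 3)]
    matrix, dropped = build_matrix([pair], probes)
    assert matrix.values.empty
    assert len(dropped) == 1 and "no_probe" in dropped[0].flags


def test_matrix_equals_plain_medians_without_outliers():
    pair = _demo_pair()
    probes = []
    for pid, (s, e) in (("a", (0, 120)), ("b", (100, 160)), ("c", (500, 560))):
        for t, base in (("liver", 10.0), ("heart", 40.0)):
            for rep, mult in ((1, 0.9), (2, 1.0), (3, 1.1)):
                probes.append(_probe(pid, s, e, t, rep, base * mult))
    matrix, dropped = build_matrix([pair], probes, tissues=["heart", "liver"])
    assert not dropped
    assert matrix.excluded_above == 0 and matrix.excluded_below == 0
    # each probe's replicate median is base * 1.0; P1 combines probes a,b
    assert matrix.values.loc["g:P1", "liver"] == pytest.approx(10.0)
    assert matrix.values.loc["g:P1", "heart"] == pytest.approx(40.0)
    assert matrix.values.loc["g:P2", "liver"] == pytest.approx(10.0)


def test_all_zero_probe_summarizes_to_zero():
    pair = _demo_pair()
    probes = [
        _probe(pid, s, e, "liver", rep, 0.0)
        for pid, (s, e) in (("a", (0, 120)), ("c", (500, 560)))
        for rep in (1, 2, 3)
    ]
    matrix, _ = build_matrix([pair], probes, tissues=["liver"])
    assert matrix.values.loc["g:P1", "liver"] == 0.0


def test_missing_tissue_for_probe_raises():
    pair = _demo_pair()
    probes = [_probe("a", 0, 120, "liver", r, 5.0) for r in (1, 2, 3)]
    probes += [_probe("c", 500, 560, "liver", r, 5.0) for r in (1, 2, 3)]
    with pytest.raises(ValueError, match="heart"):
        build_matrix([pair], probes, tissues=["liver", "heart"])


def test_planted_outlier_fraction_recovered(rng):
    """~5% planted 'above' replicates are excluded at ~5%."""
    from promoterome.simulate import SimConfig, plant_expression

    cfg = SimConfig(outlier_above_rate=0.05, outlier_below_rate=0.0)
    means = {t: 30.0 for t in cfg.tissues}
    specs = [
        (f"p{i}", GenomicInterval("chr1", 0, 25, "+"), means) for i in range(400)
    ]
    probes, truth = plant_expression(specs, cfg, rng)
    by_key = {}
    for p in probes:
        by_key.setdefault((p.probe_id, p.tissue), []).append(p.intensity)
    n_above = n_total = 0
    for values in by_key.values():
        _, labels = summarize_replicates(values)
        n_above += labels.count("above")
        n_total += len(labels)
    assert n_above / n_total == pytest.approx(0.05, abs=0.01)


def test_tissue_summary_correlations():
    import pandas as pd

    from promoterome.expression import ExpressionMatrix

    gen = np.random.default_rng(7)
    n = 1000
    p1 = gen.lognormal(3, 1, n)
    p2 = gen.lognormal(3, 1, n)  # independent
    rows = {}
    for i in range(n):
        rows[f"g{i:04d}:P1"] = [p1[i], p1[i]]
        rows[f"g{i:04d}:P2"] = [p1[i], p2[i]]  # t1 identical, t2 independent
    values = pd.DataFrame.from_dict(rows, orient="index", columns=["t1", "t2"])
    matrix = ExpressionMatrix(values=values, excluded_above=0, excluded_below=0)
    summary = tissue_summary(matrix)
    assert summary.loc["t1", "pearson_r"] == pytest.approx(1.0)
    assert abs(summary.loc["t2", "pearson_r"]) < 0.1
    assert summary.loc["t1", "p1_median"] == pytest.approx(np.median(p1))


def test_constant_vector_correlation_is_missing():
    import pandas as pd

    from promoterome.expression import ExpressionMatrix

    values = pd.DataFrame.from_dict(
        {"a:P1": [1.0], "a:P2": [5.0], "b:P1": [2.0], "b:P2": [5.0]},
        orient="index",
        columns=["t1"],
    )
    matrix = ExpressionMatrix(values=values, excluded_above=0, excluded_below=0)
    assert np.isnan(tissue_summary(matrix).loc["t1", "pearson_r"])
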