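"""Entropy scores, tissue preferences and the shared-preference model."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from promoterome.specificity import (
    SpecificityRecord,
    classify_entropy,
    entropy,
    entropy_correlation,
    expected_shared_pairs,
    observed_shared_pairs,
    shared_preference_report,
    shared_preference_test,
    tissue_preference,
)

LOG2_11 = math.log2(11)

# printed most-preferred promoter counts of the 11-tissue reference panel
PANEL_COUNTS = {
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


def test_uniform_vector_attains_maximal_entropy():
    assert entropy([7.0] * 11) == pytest.approx(LOG2_11, abs=1e-12)


def test_pseudocount_forces_uniformity_on_zero_vector():
    assert entropy([0.0] * 11, pseudocount=5) == pytest.approx(LOG2_11, abs=1e-12)
    assert entropy([0.0] * 11, pseudocount=5, statistic="q_max") == pytest.approx(
        2 * LOG2_11, abs=1e-12
    )


def test_single_dominant_tissue_scores_low():
    # pancreas-only expression profile: 2805 vs 0.1-7.38 elsewhere
    e = [2805, 0.1, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 7.38]
    assert entropy(e, pseudocount=5) < 0.5


def test_negative_intensity_rejected():
    with pytest.raises(ValueError):
        entropy([1.0, -0.1, 3.0])


def test_entropy_decreases_when_mass_concentrates():
    e = np.array([10.0] * 11)
    h0 = entropy(e)
    e[0] += 5.0
    e[1] -= 5.0  # move mass from a below-average tissue to the maximal one
    assert entropy(e) < h0


def test_normalized_probabilities_sum_to_one():
    e = np.array([0.0, 3.0, 900.0, 2.2])
    p = (e + 5) / (e + 5).sum()
    assert p.sum() == pytest.approx(1.0)
    assert entropy(e) == pytest.approx(float(-(p * np.log2(p)).sum()))


@pytest.mark.parametrize(
    "score,expected",
    [
        (2.9, "tissue_specific"),
        (3.0, "heterogeneous"),
        (5.0, "heterogeneous"),
        (7.0, "uniform"),
        (10.0, "uniform"),
    ],
)
def test_entropy_class_thresholds(score, expected):
    assert classify_entropy(score) == expected


def test_tissue_preference_over_median():
    row = pd.Series(
        {f"t{i}": 10.0 for i in range(2, 12)} | {"t1": 100.0}
    )
    preferred, most = tissue_preference(row)
    assert preferred == frozenset({"t1"}) and most == "t1"
    uniform = pd.Series({f"t{i}": 10.0 for i in range(11)})
    preferred, most = tissue_preference(uniform)
    assert preferred == frozenset() and most is None
    two = pd.Series({f"t{i}": 10.0 for i in range(2, 11)} | {"t0": 90.0, "t1": 50.0})
    preferred, most = tissue_preference(two)
    assert preferred == frozenset({"t0", "t1"}) and most == "t0"


def test_expected_pairs_worked_examples():
    assert round(expected_shared_pairs(677, 2894, 1447), 1) == 79.2
    assert round(expected_shared_pairs(447, 2894, 1447), 1) == 34.5
    assert expected_shared_pairs(0, 2894, 1447) == 0.0
    with pytest.warns(UserWarning):
        expected_shared_pairs(10, 100, 60)


def test_expected_pairs_panel_total():
    total = sum(expected_shared_pairs(c, 2894, 1447) for c in PANEL_COUNTS.values())
    assert total == pytest.approx(123.8, abs=0.1)


def _rec(gene, which, most, h=3.0):
    pref = frozenset() if most is None else frozenset({most})
    return SpecificityRecord(f"{gene}:{which}", h, "heterogeneous", pref, most)


def test_observed_shared_pairs_counts_matching_genes():
    records = []
    for i in range(10):
        shared = i < 3
        records.append(_rec(f"g{i}", "P1", "liver" if shared or i == 5 else None))
        records.append(_rec(f"g{i}", "P2", "liver" if shared else None))
    counts = observed_shared_pairs(records)
    assert counts == {"liver": 3}


def test_unpaired_promoter_raises():
    with pytest.raises(ValueError, match="unpaired"):
        observed_shared_pairs([_rec("g1", "P1", None)])


def test_chi_square_goodness_of_fit_values():
    chi2, p = shared_preference_test(111, expected_shared_pairs(677, 2894, 1447), 1447)
    assert p == pytest.approx(2.36e-4, rel=0.15)
    _, p_total = shared_preference_test(237, 123.8, 1447)
    assert p_total == pytest.approx(2.1e-26, rel=0.5)
    chi2_eq, p_eq = shared_preference_test(100.0, 100.0, 1447)
    assert chi2_eq == 0 and p_eq == 1


def test_chi_square_matches_library_oracle():
    """Hand-built statistic equals scipy's two-category GOF to 6 sig digits."""
    for o, e, g in [(111, 79.17, 1447), (23, 6.2, 1447), (4, 0.237, 1447), (73, 34.5, 1447)]:
        chi2, p = shared_preference_test(o, e, g)
        ref = stats.chisquare([o, g - o], [e, g - e])
        assert chi2 == pytest.approx(float(ref.statistic), rel=1e-6)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-6)


def test_invalid_expected_rejected():
    with pytest.raises(ValueError):
        shared_preference_test(5, 0.0, 100)


def test_entropy_correlation_cases():
    identical = [r for i in range(10) for r in (_rec(f"g{i}", "P1", None, h=float(i)),
                                                _rec(f"g{i}", "P2", None, h=float(i)))]
    assert entropy_correlation(identical) == pytest.approx(1.0)

    gen = np.random.default_rng(11)
    a, b = gen.normal(5, 1, 1000), gen.normal(5, 1, 1000)
    independent = [r for i in range(1000) for r in (_rec(f"g{i:04d}", "P1", None, h=a[i]),
                                                    _rec(f"g{i:04d}", "P2", None, h=b[i]))]
    assert abs(entropy_correlation(independent)) < 0.1

    anti = [r for i in range(10) for r in (_rec(f"g{i}", "P1", None, h=float(i)),
                                           _rec(f"g{i}", "P2", None, h=float(-i)))]
    assert entropy_correlation(anti) < 0

    constant = [r for i in range(5) for r in (_rec(f"g{i}", "P1", None, h=1.0),
                                              _rec(f"g{i}", "P2", None, h=float(i)))]
    assert np.isnan(entropy_correlation(constant))


def test_shared_preference_report_consistency():
    tissues = sorted(PANEL_COUNTS)
    gen = np.random.default_rng(3)
    n = 300
    p1 = [tissues[i % 11] if i % 3 else None for i in range(n)]
    p2 = [tissues[(i + gen.integers(0, 3)) % 11] if i % 4 else None for i in range(n)]
    rep = shared_preference_report(p1, p2, tissues)
    body = rep.drop(index="Total")
    total = rep.loc["Total"]
    assert total["count_most_preferred"] == body["count_most_preferred"].sum()
    assert total["expected_pairs"] == pytest.approx(body["expected_pairs"].sum())
    assert total["observed_pairs"] == body["observed_pairs"].sum()
    # percent columns consistent with counts over 2G promoters
    for _, row in body.iterrows():
        assert row["pct_most_preferred"] == pytest.approx(
            100.0 * row["count_most_preferred"] / (2 * n)
        )
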