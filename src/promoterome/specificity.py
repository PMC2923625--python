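"""Tissue-specificity scores and shared tissue-preference statistics.

Specificity is scored by pseudocount-regularized Shannon entropy over the
tissue panel: with intensities e_t and pseudocount c, p_t = (e_t + c) / sum_u
(e_u + c) and H = -sum_t p_t log2 p_t.  A Schug-style variant q_max = H -
log2(max_t p_t) is also available.  Low entropy marks tissue-specific
expression, high entropy uniform expression.

Coordinated tissue preference of P1/P2 promoter pairs is tested against an
independence model: if a fraction q_t of all promoters most-prefers tissue t,
q_t^2 of gene pairs are expected to share it; a two-category chi-square
goodness-of-fit (df = 1) compares observed and expected pair counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

TISSUE_SPECIFIC = "tissue_specific"
HETEROGENEOUS = "heterogeneous"
UNIFORM = "uniform"


@dataclass(frozen=True)
class SpecificityRecord:
    """Per-promoter entropy, class, and tissue-preference calls."""

    promoter_id: str
    entropy: float
    entropy_class: str
    preferred_tissues: frozenset[str]
    most_preferred: Optional[str]

    @property
    def gene_id(self) -> str:
        return self.promoter_id.rsplit(":", 1)[0]

    @property
    def which(self) -> str:
        return self.promoter_id.rsplit(":", 1)[1]


@dataclass(frozen=True)
class SharedPreferenceResult:
    """Per-tissue observed vs expected shared-preference pair counts."""

    tissue: str
    count_2x: int
    count_most_preferred: int
    expected_pairs: float
    observed_pairs: int
    chi2: float
    p_value: float


def entropy(
    e: Sequence[float], pseudocount: float = 5.0, statistic: str = "shannon"
) -> float:
    """Entropy score of an intensity vector over >= 2 tissues.

    'shannon' returns H in bits (range [0, log2 n]); 'q_max' returns
    H - log2(max_t p_t) (range [0, 2 log2 n]).  The pseudocount guards against
    misleading specificity at near-zero intensities.
    """
    e = np.asarray(e, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("need a vector of >= 2 intensities")
    if np.any(e < 0):
        raise ValueError("negative intensity")
    p = e + pseudocount
    p = p / p.sum()
    h = float(-(p * np.log2(p)).sum())
    if statistic == "shannon":
        return h
    if statistic == "q_max":
        return h - float(np.log2(p.max()))
    raise ValueError(f"unknown statistic: {statistic!r}")


def classify_entropy(score: float, low: float = 3.0, high: float = 7.0) -> str:
    """tissue_specific below *low*, uniform at/above *high*, else heterogeneous."""
    if not low < high:
        raise ValueError("require low < high")
    if score < low:
        return TISSUE_SPECIFIC
    if score >= high:
        return UNIFORM
    return HETEROGENEOUS


def tissue_preference(
    row: Union[pd.Series, Mapping[str, float]],
    factor: float = 2.0,
    center: str = "median",
) -> tuple[frozenset[str], Optional[str]]:
    """Tissues whose signal exceeds *factor* x the row center, and the top one.

    A tissue is preferred when its intensity is strictly greater than
    factor * center(row) (center: 'median' or 'mean' over all tissues).  The
    most-preferred tissue is the argmax intensity provided it passes the
    threshold; argmax ties break by tissue name.
    """
    if factor <= 1:
        raise ValueError("factor must exceed 1")
    series = pd.Series(row, dtype=float)
    if center == "median":
        c = float(series.median())
    elif center == "mean":
        c = float(series.mean())
    else:
        raise ValueError(f"unknown center: {center!r}")
    threshold = factor * c
    preferred = frozenset(series.index[series > threshold])
    most: Optional[str] = None
    if preferred:
        top = sorted(series.index[series == series.max()])[0]
        if top in preferred:
            most = top
    return preferred, most


def build_specificity_records(
    values: pd.DataFrame,
    pseudocount: float = 5.0,
    statistic: str = "shannon",
    low: float = 3.0,
    high: float = 7.0,
    factor: float = 2.0,
    center: str = "median",
) -> list[SpecificityRecord]:
    """Score every promoter row of an expression matrix."""
    records = []
    for prom, row in values.iterrows():
        h = entropy(row.to_numpy(), pseudocount=pseudocount, statistic=statistic)
        preferred, most = tissue_preference(row, factor=factor, center=center)
        records.append(
            SpecificityRecord(
                promoter_id=str(prom),
                entropy=h,
                entropy_class=classify_entropy(h, low=low, high=high),
                preferred_tissues=preferred,
                most_preferred=most,
            )
        )
    return records


def expected_shared_pairs(
    count_most_preferred: int, n_promoters: int, n_genes: int
) -> float:
    """Expected P1/P2 pairs sharing a most-preferred tissue under independence.

    With q = count / n_promoters the pooled per-promoter frequency, the
    expectation is q^2 * n_genes.  The value is returned unrounded.
    """
    if not 0 <= count_most_preferred <= n_promoters:
        raise ValueError("count outside [0, n_promoters]")
    if n_promoters != 2 * n_genes:
        warnings.warn(
            "independence model assumes n_promoters == 2 * n_genes (pooled "
            "P1/P2 frequency)",
            stacklevel=2,
        )
    q = count_most_preferred / n_promoters
    return q * q * n_genes


def observed_shared_pairs(records: Sequence[SpecificityRecord]) -> dict[str, int]:
    """Count genes whose P1 and P2 share the same most-preferred tissue."""
    by_gene: dict[str, dict[str, SpecificityRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, {})[r.which] = r
    counts: dict[str, int] = {}
    for gene, members in by_gene.items():
        if set(members) != {"P1", "P2"}:
            raise ValueError(f"gene {gene}: unpaired promoter records")
        t1 = members["P1"].most_preferred
        t2 = members["P2"].most_preferred
        if t1 is not None and t1 == t2:
            counts[t1] = counts.get(t1, 0) + 1
    return counts


def shared_preference_test(
    observed: int, expected: float, n_genes: int
) -> tuple[float, float]:
    """Two-category chi-square goodness of fit (df = 1) on pair counts.

    chi2 = (O-E)^2/E + ((G-O)-(G-E))^2/(G-E); p is the upper tail of
    chi-square with one degree of freedom.
    """
    if expected <= 0:
        raise ValueError("expected must be positive")
    if expected >= n_genes:
        raise ValueError("expected must be below n_genes")
    g = n_genes
    chi2 = (observed - expected) ** 2 / expected + (
        (g - observed) - (g - expected)
    ) ** 2 / (g - expected)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def entropy_correlation(records: Sequence[SpecificityRecord]) -> float:
    """Pearson r between paired P1 and P2 entropy scores (NaN if degenerate)."""
    by_gene: dict[str, dict[str, float]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, {})[r.which] = r.entropy
    x, y = [], []
    for gene in sorted(by_gene):
        members = by_gene[gene]
        if set(members) == {"P1", "P2"}:
            x.append(members["P1"])
            y.append(members["P2"])
    if len(x) < 2:
        raise ValueError("need >= 2 complete pairs")
    x, y = np.asarray(x), np.asarray(y)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def shared_preference_report(
    p1_most: Sequence[Optional[str]],
    p2_most: Sequence[Optional[str]],
    tissues: Sequence[str],
    p1_preferred: Optional[Sequence[frozenset]] = None,
    p2_preferred: Optional[Sequence[frozenset]] = None,
) -> pd.DataFrame:
    """Tabulate per-tissue preference counts, expected/observed pairs and tests.

    *p1_most* / *p2_most* are aligned per-gene most-preferred labels (None =
    no preference); the optional preferred-set sequences feed the 2x-threshold
    count column (defaults to the most-preferred labels when absent).
    Returns one row per tissue plus a Total row.
    """
    n_genes = len(p1_most)
    if len(p2_most) != n_genes:
        raise ValueError("p1/p2 label lengths differ")
    n_prom = 2 * n_genes
    if p1_preferred is None:
        p1_preferred = [frozenset() if t is None else frozenset({t}) for t in p1_most]
    if p2_preferred is None:
        p2_preferred = [frozenset() if t is None else frozenset({t}) for t in p2_most]

    rows = []
    total_2x = total_most = total_obs = 0
    total_exp = 0.0
    for t in tissues:
        c2x = sum(t in s for s in p1_preferred) + sum(t in s for s in p2_preferred)
        cmost = sum(m == t for m in p1_most) + sum(m == t for m in p2_most)
        exp = expected_shared_pairs(cmost, n_prom, n_genes)
        obs = sum(a == t and b == t for a, b in zip(p1_most, p2_most))
        if 0 < exp < n_genes:
            chi2, p = shared_preference_test(obs, exp, n_genes)
        else:
            chi2, p = float("nan"), float("nan")
        rows.append(
            {
                "tissue": t,
                "count_2x": c2x,
                "pct_2x": 100.0 * c2x / n_prom,
                "count_most_preferred": cmost,
                "pct_most_preferred": 100.0 * cmost / n_prom,
                "expected_pairs": exp,
                "observed_pairs": obs,
                "chi2": chi2,
                "p_value": p,
            }
        )
        total_2x += c2x
        total_most += cmost
        total_exp += exp
        total_obs += obs
    rows.append(
        {
            "tissue": "Total",
            "count_2x": total_2x,
            "pct_2x": 100.0 * total_2x / n_prom,
            "count_most_preferred": total_most,
            "pct_most_preferred": 100.0 * total_most / n_prom,
            "expected_pairs": total_exp,
            "observed_pairs": total_obs,
            "chi2": float("nan"),
            "p_value": float("nan"),
        }
    )
    return pd.DataFrame(rows).set_index("tissue")
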