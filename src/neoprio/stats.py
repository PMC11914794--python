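"""Exact and rank-based statistics for pipeline comparison.

Two-sided Fisher's exact test (probability-mass convention: the p-value
sums the probabilities of every table with the observed margins whose
hypergeometric probability does not exceed the observed table's) and the
Mann-Whitney U test (exact null distribution for small tie-free samples,
normal approximation with tie and continuity corrections otherwise), plus
the contingency-table construction and percentile-rank group comparison
used to judge long vs short peptides and the individual ranking metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import fisher_exact, mannwhitneyu

from .errors import NeoprioError
from .prioritize import RankedVariant
from .screen import CohortSummary

#: largest tie-free n1+n2 for which the exact Mann-Whitney null is used
MW_EXACT_MAX_N = 16

RANK_METRICS = ("tpm", "dna_vaf", "rna_vaf", "sum")

#: pool class membership for the long-vs-short re-stratification
LONG_POOLS = ("ipv_long", "tesla_long")
SHORT_POOLS = ("tesla_short", "ipv_short")


@dataclass(frozen=True)
class Contingency2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise NeoprioError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise NeoprioError("contingency table is all zero")

    @property
    def table(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class RankComparison:
    """Mann-Whitney comparison of positive vs negative percentile ranks."""

    metric: str
    positive_values: tuple[float, ...]
    negative_values: tuple[float, ...]
    u_statistic: float
    p_value: float


def fisher_exact_two_sided(t: Contingency2x2) -> float:
    """Two-sided Fisher's exact p-value (probability-mass method)."""
    return float(min(1.0, fisher_exact(t.table, alternative="two-sided")[1]))


def mann_whitney_u(x: Sequence[float],
                   y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (of *x*, midranks for ties) and two-sided p.

    The exact null distribution is used when n1 + n2 <= 16 and there are
    no ties across the pooled sample; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise NeoprioError("mann_whitney_u requires two non-empty groups")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and pooled.size <= MW_EXACT_MAX_N) \
        else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def build_length_contingency(summary: CohortSummary,
                             cytokine: str) -> Contingency2x2:
    """Re-stratify the four pool classes by peptide length.

    Row 1 pools the long classes (ipv_long + tesla_long), row 2 the short
    classes (tesla_short + ipv_short); columns are positive / negative
    counts for the requested cytokine.
    """
    missing = [p for p in LONG_POOLS + SHORT_POOLS
               if (p, cytokine) not in summary.pools]
    if missing:
        raise NeoprioError(
            f"summary lacks pool class(es) for {cytokine}: "
            f"{', '.join(missing)}")
    long_pos = sum(summary.get(p, cytokine).n_positive for p in LONG_POOLS)
    long_neg = sum(summary.get(p, cytokine).n_negative for p in LONG_POOLS)
    short_pos = sum(summary.get(p, cytokine).n_positive for p in SHORT_POOLS)
    short_neg = sum(summary.get(p, cytokine).n_negative for p in SHORT_POOLS)
    return Contingency2x2(a=long_pos, b=long_neg, c=short_pos, d=short_neg)


def _metric_value(rv: RankedVariant, metric: str) -> float:
    if metric == "tpm":
        return rv.tpm_pctile
    if metric == "dna_vaf":
        return rv.dna_vaf_pctile
    if metric == "rna_vaf":
        return rv.rna_vaf_pctile
    if metric == "sum":
        return rv.pctile_sum
    raise NeoprioError(
        f"unknown metric {metric!r}; expected one of {RANK_METRICS}")


def compare_metric_ranks(
    candidates: Sequence[tuple[RankedVariant, bool]],
    metric: str,
) -> RankComparison:
    """Compare a percentile-rank metric between immunogenicity-positive
    and negative candidates (percentiles must already be per-donor)."""
    pos = [_metric_value(rv, metric) for rv, label in candidates if label]
    neg = [_metric_value(rv, metric) for rv, label in candidates if not label]
    if not pos or not neg:
        raise NeoprioError(
            "compare_metric_ranks requires at least one positive and one "
            "negative candidate")
    u, p = mann_whitney_u(pos, neg)
    return RankComparison(
        metric=metric, positive_values=tuple(pos),
        negative_values=tuple(neg), u_statistic=u, p_value=p)


def compare_pool_to_baseline(summary: CohortSummary, pool: str,
                             baseline: str, cytokine: str) -> float:
    """Fisher p for one pool's positive/negative counts against a
    baseline pool (the short-peptide class-I pool in the study design)."""
    for name in (pool, baseline):
        if (name, cytokine) not in summary.pools:
            raise NeoprioError(f"summary lacks pool {name!r} for {cytokine}")
    p1 = summary.get(pool, cytokine)
    p2 = summary.get(baseline, cytokine)
    table = Contingency2x2(a=p1.n_positive, b=p1.n_negative,
                           c=p2.n_positive, d=p2.n_negative)
    return fisher_exact_two_sided(table)
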