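"""Variant filtering and ranking for the long-peptide (IPV) pipeline.

A somatic variant is carried forward when it satisfies six conjunctive
criteria on its read evidence:

1. tumor DNA VAF >= 2%
2. the protein annotation denotes a missense single-residue substitution
3. tumor DNA VAF >= normal DNA VAF (tumor/normal ratio >= 1; a variant
   absent from the normal sample passes)
4. the variant is observed in RNA at least once
5. normal DNA VAF <= 5% and tumor DNA VAF >= 5% (both bounds inclusive)
6. both tumor and normal DNA positions are covered by >= 10 reads

Criteria 1 and 5 overlap (5 is the binding tumor-VAF bound); both are
evaluated and reported so a filter report shows each predicate on its own.

Passing variants are ranked per patient by RNA VAF (descending), then TPM
(descending), then tumor genotype priority (ascending: homozygous-alt
first, heterozygous, homozygous-ref last), with input order as the final
deterministic tie-break. Per-donor midrank percentiles of TPM, DNA VAF and
RNA VAF are attached as reporting outputs; they are not part of the sort
key.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .hgvs import is_missense
from .io import VariantTableRow

#: tumor genotype -> sort priority (lower sorts first)
GENOTYPE_PRIORITY = {"hom_alt": 1, "het": 2, "hom_ref": 3}

TUMOR_VAF_MIN = 0.02
TUMOR_VAF_STRONG_MIN = 0.05
NORMAL_VAF_MAX = 0.05
MIN_DEPTH = 10


@dataclass(frozen=True)
class VariantEvidence:
    """Derived per-variant quantities the filters and ranking act on."""

    tumor_dna_vaf: float
    normal_dna_vaf: float
    rna_vaf: float
    rna_alt: int
    tumor_dna_depth: int
    normal_dna_depth: int
    tpm: float
    genotype_priority: int
    zero_depth: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of the six filter predicates for one variant."""

    c1_tumor_vaf_ge_2pct: bool
    c2_nonsynonymous: bool
    c3_tumor_ge_normal_ratio: bool
    c4_rna_observed: bool
    c5_normal_le_5pct_and_tumor_ge_5pct: bool
    c6_coverage_ge_10: bool

    @property
    def overall_pass(self) -> bool:
        return (self.c1_tumor_vaf_ge_2pct and self.c2_nonsynonymous
                and self.c3_tumor_ge_normal_ratio and self.c4_rna_observed
                and self.c5_normal_le_5pct_and_tumor_ge_5pct
                and self.c6_coverage_ge_10)


@dataclass(frozen=True)
class RankedVariant:
    """A passing variant with its rank and per-donor percentile metrics."""

    row: VariantTableRow
    evidence: VariantEvidence
    ipv_rank: int
    tpm_pctile: float
    dna_vaf_pctile: float
    rna_vaf_pctile: float

    @property
    def pctile_sum(self) -> float:
        return self.tpm_pctile + self.dna_vaf_pctile + self.rna_vaf_pctile


def _vaf(alt: int, depth: int) -> tuple[float, bool]:
    if depth == 0:
        return 0.0, True
    return alt / depth, False


def compute_evidence(row: VariantTableRow) -> VariantEvidence:
    """Derive VAFs and genotype priority from raw counts.

    A zero read depth yields VAF 0.0 and is recorded in ``zero_depth``
    rather than raising: downstream filters treat an uncovered site as
    providing no support.
    """
    t_vaf, t_zero = _vaf(row.tumor_dna_alt, row.tumor_dna_depth)
    n_vaf, n_zero = _vaf(row.normal_dna_alt, row.normal_dna_depth)
    r_vaf, r_zero = _vaf(row.rna_alt, row.rna_depth)
    flags = set()
    if t_zero:
        flags.add("tumor_dna")
    if n_zero:
        flags.add("normal_dna")
    if r_zero:
        flags.add("rna")
    return VariantEvidence(
        tumor_dna_vaf=t_vaf,
        normal_dna_vaf=n_vaf,
        rna_vaf=r_vaf,
        rna_alt=row.rna_alt,
        tumor_dna_depth=row.tumor_dna_depth,
        normal_dna_depth=row.normal_dna_depth,
        tpm=row.tpm,
        genotype_priority=GENOTYPE_PRIORITY[row.tumor_genotype],
        zero_depth=frozenset(flags),
    )


def apply_ipv_filters(
    rows: list[VariantTableRow],
) -> list[tuple[VariantTableRow, FilterVerdict]]:
    """Evaluate the six criteria on every row, preserving input order."""
    out = []
    for row in rows:
        ev = compute_evidence(row)
        verdict = FilterVerdict(
            c1_tumor_vaf_ge_2pct=ev.tumor_dna_vaf >= TUMOR_VAF_MIN,
            c2_nonsynonymous=is_missense(row.hgvs_protein),
            c3_tumor_ge_normal_ratio=ev.tumor_dna_vaf >= ev.normal_dna_vaf,
            c4_rna_observed=row.rna_alt >= 1,
            c5_normal_le_5pct_and_tumor_ge_5pct=(
                ev.normal_dna_vaf <= NORMAL_VAF_MAX
                and ev.tumor_dna_vaf >= TUMOR_VAF_STRONG_MIN),
            c6_coverage_ge_10=(row.tumor_dna_depth >= MIN_DEPTH
                               and row.normal_dna_depth >= MIN_DEPTH),
        )
        out.append((row, verdict))
    return out


def passing_rows(rows: list[VariantTableRow]) -> list[VariantTableRow]:
    """Rows surviving all six filters, in input order."""
    return [r for r, v in apply_ipv_filters(rows) if v.overall_pass]


def percentile_ranks(values) -> np.ndarray:
    """Midrank percentiles: ``(rank - 0.5) / n * 100``, ties sharing the
    mean rank. The output mean is exactly 50 for tie-free input and the
    result is invariant under any strictly increasing transform."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile_ranks requires at least one value")
    ranks = rankdata(values, method="average")
    return (ranks - 0.5) / values.size * 100.0


def rank_variants(rows: list[VariantTableRow]) -> list[RankedVariant]:
    """Rank one patient's passing variants and attach percentile metrics.

    Sort is stable and lexicographic: RNA VAF desc, TPM desc, genotype
    priority asc, then original input order.
    """
    if not rows:
        return []
    patients = {r.patient_id for r in rows}
    if len(patients) > 1:
        raise ValueError(
            f"rank_variants expects a single patient, got {sorted(patients)}")
    evidence = [compute_evidence(r) for r in rows]
    order = sorted(
        range(len(rows)),
        key=lambda i: (-evidence[i].rna_vaf, -evidence[i].tpm,
                       evidence[i].genotype_priority, i),
    )
    tpm_p = percentile_ranks([e.tpm for e in evidence])
    dna_p = percentile_ranks([e.tumor_dna_vaf for e in evidence])
    rna_p = percentile_ranks([e.rna_vaf for e in evidence])
    return [
        RankedVariant(
            row=rows[i], evidence=evidence[i], ipv_rank=rank,
            tpm_pctile=float(tpm_p[i]),
            dna_vaf_pctile=float(dna_p[i]),
            rna_vaf_pctile=float(rna_p[i]),
        )
        for rank, i in enumerate(order, start=1)
    ]


def top_n(ranked: list[RankedVariant], n: int) -> list[RankedVariant]:
    """First ``min(n, len)`` entries by rank (the screen tests ten)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return sorted(ranked, key=lambda r: r.ipv_rank)[:n]
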