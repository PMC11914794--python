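"""End-to-end orchestration over the library modules.

Glue used by the command-line interface, the test suite and the
reproduction script: prioritize a cohort, design the four candidate
classes, score the class-I candidates, plate and analyze a synthetic
screen, and compare the pipelines. Each step is a thin composition of
the per-module operations; nothing here adds behaviour of its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import design as dz
from . import prioritize as pz
from . import screen as sc
from . import simulate as sim
from . import stats as st
from . import tesla as ts
from .io import VariantTableRow

#: HLA class I alleles assumed for synthetic patients (predictions are
#: mocked, so only the number of alleles matters, not their identity)
DEFAULT_ALLELES = ("HLA-A*02:01", "HLA-A*01:01", "HLA-B*07:02")

POOL_CLASSES = ("ipv_long", "ipv_short", "tesla_short", "tesla_long")


@dataclass
class PatientDesign:
    """Everything designed for one patient."""

    patient_id: str
    ranked: list[pz.RankedVariant]
    tested: list[pz.RankedVariant]
    ipv_long: list[dz.PeptideCandidate] = field(default_factory=list)
    ipv_short: list[dz.PeptideCandidate] = field(default_factory=list)
    tesla_short: list[dz.PeptideCandidate] = field(default_factory=list)
    tesla_long: list[dz.PeptideCandidate] = field(default_factory=list)
    tesla_metrics: list[ts.TeslaMetrics] = field(default_factory=list)

    def pool_genes(self, klass: str) -> tuple[str, ...]:
        members = getattr(self, klass)
        genes = []
        for cand in members:
            gene = cand.source_variant.split(":", 1)[-1]
            if gene not in genes:
                genes.append(gene)
        return tuple(genes)


def prioritize_cohort(variants: Sequence[VariantTableRow],
                      top: int = 10) -> dict[str, PatientDesign]:
    """Filter and rank per patient; ``tested`` is the top-*top* cut."""
    by_patient: dict[str, list[VariantTableRow]] = {}
    for row in variants:
        by_patient.setdefault(row.patient_id, []).append(row)
    out = {}
    for patient, rows in by_patient.items():
        ranked = pz.rank_variants(pz.passing_rows(rows))
        out[patient] = PatientDesign(
            patient_id=patient, ranked=ranked,
            tested=pz.top_n(ranked, top))
    return out


def design_patient(pd: PatientDesign, proteins: dict[str, str],
                   alleles: Sequence[str], predictor,
                   reference_epitopes: Sequence[str],
                   params: Optional[ts.ForeignnessParams] = None,
                   thresholds: Optional[ts.TeslaThresholds] = None,
                   top: int = 10) -> PatientDesign:
    """Design all four candidate classes for one patient's tested variants.

    The tesla_short pool keeps the top-*top* threshold-passing candidates
    by the class-I ranking; tesla_long lengthens each of those back to
    its containing 20-mer (unique sequences only).
    """
    all_shorts: list[dz.PeptideCandidate] = []
    tpm_by_source: dict[str, float] = {}
    for rv in pd.tested:
        ctx = dz.context_for_variant(rv.row, proteins)
        source = f"{pd.patient_id}:{rv.row.gene}"
        pd.ipv_long.extend(dz.design_ipv_long(ctx, source=source))
        shorts = dz.enumerate_short_spanning(ctx, source=source)
        all_shorts.extend(shorts)
        tpm_by_source[source] = rv.row.tpm

    pd.ipv_short = dz.select_ipv_short(pd.ipv_long, alleles, predictor,
                                       n=top)
    metrics = [
        ts.compute_tesla_metrics(
            cand, alleles, predictor, tpm_by_source[cand.source_variant],
            reference_epitopes, params, thresholds)
        for cand in all_shorts
    ]
    passing = [m for m in metrics if m.overall_pass]
    pd.tesla_metrics = ts.tesla_rank(passing)
    pd.tesla_short = [m.peptide for m in pd.tesla_metrics[:top]]

    seen: set[str] = set()
    for short in pd.tesla_short:
        try:
            long_pep = dz.lengthen_tesla(short, pd.ipv_long)
        except Exception as exc:  # clamped windows may not contain the short
            warnings.warn(str(exc))
            continue
        if long_pep.sequence not in seen:
            seen.add(long_pep.sequence)
            pd.tesla_long.append(long_pep)
    return pd


@dataclass
class EndToEndResult:
    config: sim.SimulationConfig
    cohort: sim.Cohort
    designs: dict[str, PatientDesign]
    pools: list[sim.PoolSpec]
    calls: list[sc.ScreenCall]
    summary: sc.CohortSummary
    length_fisher: dict[str, float]  # cytokine -> p (when computable)
    rank_comparisons: dict[str, st.RankComparison]


def run_end_to_end(config: sim.SimulationConfig,
                   predictor: Optional[ts.Predictor] = None,
                   alleles: Sequence[str] = DEFAULT_ALLELES,
                   top: int = 10,
                   include_singles: bool = False) -> EndToEndResult:
    """Simulate a cohort and push it through both pipelines and the screen.

    The foreignness reference set includes exact copies of each patient's
    top-variant short peptides so that, as in a curated epitope database,
    some candidates have near-identical known epitopes.
    """
    predictor = predictor or ts.MockPredictor(seed=config.seed)
    cohort = sim.simulate_cohort(config)
    designs = prioritize_cohort(cohort.variants, top=top)

    seeded_epitopes: list[str] = []
    for pd in designs.values():
        if pd.tested:
            ctx = dz.context_for_variant(pd.tested[0].row, cohort.proteins)
            shorts = dz.enumerate_short_spanning(ctx)
            if shorts:
                seeded_epitopes.append(shorts[0].sequence)
    epitopes = sim.make_reference_epitopes(config, include=seeded_epitopes)

    pools: list[sim.PoolSpec] = []
    for patient in sorted(designs):
        pd = design_patient(designs[patient], cohort.proteins, alleles,
                            predictor, epitopes, top=top)
        for klass in POOL_CLASSES:
            genes = pd.pool_genes(klass)
            if genes:
                pools.append(sim.PoolSpec(patient_id=patient, name=klass,
                                          genes=genes))

    wells = sim.simulate_plates(pools, cohort.truth, config,
                                include_singles=include_singles)
    calls = sc.analyze_plates(wells)
    summary = sc.summarize_cohort(
        [c for c in calls if c.stimulus in POOL_CLASSES],
        pool_labels=POOL_CLASSES)

    length_fisher: dict[str, float] = {}
    for cytokine in ("IFNg", "IL5"):
        try:
            table = st.build_length_contingency(summary, cytokine)
            length_fisher[cytokine] = st.fisher_exact_two_sided(table)
        except Exception:
            continue  # a pool class may be empty in a small simulation

    labelled = [
        (rv, cohort.truth.immunogenic[(patient, rv.row.gene)])
        for patient, pd in designs.items()
        for rv in pd.ranked
    ]
    rank_comparisons = {}
    for metric in st.RANK_METRICS:
        try:
            rank_comparisons[metric] = st.compare_metric_ranks(labelled,
                                                               metric)
        except Exception:
            continue  # degenerate single-class cohort

    return EndToEndResult(
        config=config, cohort=cohort, designs=designs, pools=pools,
        calls=calls, summary=summary, length_fisher=length_fisher,
        rank_comparisons=rank_comparisons)
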