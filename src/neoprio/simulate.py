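"""Synthetic cohorts with known ground truth.

Generates everything the pipeline consumes offline: random wild-type
proteins with one implanted missense SNV each, binomially sampled
tumor/normal DNA and tumor RNA read counts at configured allele
frequencies, log-normal gene expression (with an upward multiplier for
the designated immunogenic variants, emulating the observation that
recognized variants tend to come from highly expressed genes), a
reference epitope set for foreignness scoring, and Poisson-noise
ELISpot/Fluorospot plates in which pools containing an immunogenic
variant's peptides secrete at an elevated rate.

All randomness flows from one seed through named substreams (proteins /
evidence / plates / epitopes), so regenerating one artifact never
perturbs another and identical configurations are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import io as nio
from .errors import NeoprioError
from .hgvs import AA3_TO_1

_AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
_AA20 = sorted(AA3_TO_1.values())
_NUC = ["A", "C", "G", "T"]

# substream labels -> fixed offsets mixed with the user seed
_SUBSTREAMS = {"proteins": 11, "evidence": 23, "plates": 37, "epitopes": 53}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named artifact substream."""
    return np.random.default_rng([int(seed), _SUBSTREAMS[name]])


class PlateConfig(BaseModel):
    """Spot-count model: Poisson counts per well."""

    background_rate: float = Field(default=3.0, ge=0)  # spots/well
    immunogenic_rate: float = Field(default=30.0, ge=0)  # added spots/well
    pha_rate: float = Field(default=100.0, ge=0)
    replicates: int = Field(default=3, ge=1)
    cells_per_well: int = Field(default=100_000, gt=0)


class SimulationConfig(BaseModel):
    """Cohort-scale and distributional parameters.

    Defaults describe a desk-scale cohort that is structurally faithful
    to a tumor/normal sequencing study: clonal-to-subclonal tumor VAFs
    with a floor at the callable 5% level, ~1% contamination in the
    normal, exome/RNA depths in the tens-to-hundreds, and log-normal TPM.
    """

    seed: int = 0
    n_patients: int = Field(default=4, ge=1)
    n_variants_per_patient: int = Field(default=20, ge=1)
    protein_length: tuple[int, int] = (60, 300)
    tumor_vaf_beta: tuple[float, float] = (2.0, 8.0)
    tumor_vaf_floor: float = Field(default=0.05, ge=0, le=1)
    normal_vaf: float = Field(default=0.01, ge=0, le=1)
    dna_depth: tuple[int, int] = (50, 200)
    rna_depth: tuple[int, int] = (20, 100)
    tpm_log_mean: float = 3.0
    tpm_log_sigma: float = Field(default=1.5, gt=0)
    fraction_immunogenic: float = Field(default=0.25, ge=0, le=1)
    immunogenic_tpm_multiplier: float = Field(default=4.0, gt=0)
    n_reference_epitopes: int = Field(default=50, ge=0)
    plate: PlateConfig = Field(default_factory=PlateConfig)

    @model_validator(mode="after")
    def _ranges(self) -> "SimulationConfig":
        for name in ("protein_length", "dna_depth", "rna_depth"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")
        a, b = self.tumor_vaf_beta
        if a <= 0 or b <= 0:
            raise ValueError("tumor_vaf_beta parameters must be > 0")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Which simulated variants are truly immunogenic."""

    immunogenic: dict[tuple[str, str], bool]  # (patient_id, gene) -> bool

    def pool_expected_positive(self, patient_id: str,
                               genes: Sequence[str]) -> bool:
        return any(self.immunogenic[(patient_id, g)] for g in genes)


@dataclass(frozen=True)
class PoolSpec:
    """A peptide pool to plate: a named set of member variants."""

    patient_id: str
    name: str
    genes: tuple[str, ...]


@dataclass(frozen=True)
class Cohort:
    proteins: dict[str, str]
    variants: list[nio.VariantTableRow]
    truth: GroundTruth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA20, size=length))


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Proteins, variant table and ground truth for one cohort."""
    rng_prot = substream(config.seed, "proteins")
    rng_ev = substream(config.seed, "evidence")
    proteins: dict[str, str] = {}
    variants: list[nio.VariantTableRow] = []
    truth: dict[tuple[str, str], bool] = {}
    n_imm = int(round(config.fraction_immunogenic
                      * config.n_variants_per_patient))

    for p in range(1, config.n_patients + 1):
        patient = f"P{p:02d}"
        imm_idx = set(rng_ev.choice(config.n_variants_per_patient,
                                    size=n_imm, replace=False).tolist())
        for v in range(config.n_variants_per_patient):
            gene = f"{patient}_G{v + 1:03d}"
            length = int(rng_prot.integers(config.protein_length[0],
                                           config.protein_length[1] + 1))
            protein = _random_protein(rng_prot, length)
            proteins[gene] = protein

            mut_pos = int(rng_prot.integers(1, length + 1))
            wt = protein[mut_pos - 1]
            mut = str(rng_prot.choice([a for a in _AA20 if a != wt]))
            hgvs = f"p.{_AA1_TO_3[wt]}{mut_pos}{_AA1_TO_3[mut]}"

            a, b = config.tumor_vaf_beta
            vaf = config.tumor_vaf_floor + (
                1 - config.tumor_vaf_floor) * float(rng_ev.beta(a, b))
            t_depth = int(rng_ev.integers(config.dna_depth[0],
                                          config.dna_depth[1] + 1))
            n_depth = int(rng_ev.integers(config.dna_depth[0],
                                          config.dna_depth[1] + 1))
            r_depth = int(rng_ev.integers(config.rna_depth[0],
                                          config.rna_depth[1] + 1))
            t_alt = int(rng_ev.binomial(t_depth, vaf))
            n_alt = int(rng_ev.binomial(n_depth, config.normal_vaf))
            r_alt = int(rng_ev.binomial(r_depth, vaf))

            tpm = float(rng_ev.lognormal(config.tpm_log_mean,
                                         config.tpm_log_sigma))
            is_imm = v in imm_idx
            if is_imm:
                tpm *= config.immunogenic_tpm_multiplier

            genotype = ("hom_alt" if vaf >= 0.85
                        else "het" if vaf >= 0.15 else "hom_ref")
            ref_nuc = str(rng_ev.choice(_NUC))
            alt_nuc = str(rng_ev.choice([n for n in _NUC if n != ref_nuc]))

            variants.append(nio.VariantTableRow(
                patient_id=patient,
                chrom=f"chr{(v % 22) + 1}",
                pos=1_000_000 + 100 * v + p,
                ref_allele=ref_nuc, alt_allele=alt_nuc,
                gene=gene, hgvs_protein=hgvs,
                tumor_dna_depth=t_depth, tumor_dna_alt=t_alt,
                normal_dna_depth=n_depth, normal_dna_alt=n_alt,
                rna_depth=r_depth, rna_alt=r_alt,
                tpm=tpm, tumor_genotype=genotype,
            ))
            truth[(patient, gene)] = is_imm
    return Cohort(proteins=proteins, variants=variants,
                  truth=GroundTruth(immunogenic=truth))


def simulate_plates(pools: Sequence[PoolSpec], truth: GroundTruth,
                    config: SimulationConfig,
                    include_singles: bool = False,
                    cytokines: Sequence[str] = ("IFNg", "IL5"),
                    ) -> list[nio.PlateWell]:
    """Poisson spot counts for pools, controls and (optionally) the
    single-variant deconvolution stimuli."""
    rng = substream(config.seed, "plates")
    pc = config.plate
    wells: list[nio.PlateWell] = []

    def add(patient: str, stimulus: str, cytokine: str, rate: float) -> None:
        for rep in range(1, pc.replicates + 1):
            wells.append(nio.PlateWell(
                patient_id=patient, stimulus=stimulus, cytokine=cytokine,
                replicate=rep, spot_count=int(rng.poisson(rate)),
                cells_per_well=pc.cells_per_well))

    patients = sorted({p.patient_id for p in pools})
    for patient in patients:
        for cytokine in cytokines:
            add(patient, "media", cytokine, pc.background_rate)
            add(patient, "DMSO", cytokine, pc.background_rate)
            add(patient, "PHA", cytokine, pc.pha_rate)
    for pool in pools:
        hot = truth.pool_expected_positive(pool.patient_id, pool.genes)
        rate = pc.background_rate + (pc.immunogenic_rate if hot else 0.0)
        for cytokine in cytokines:
            add(pool.patient_id, pool.name, cytokine, rate)
        if include_singles:
            for gene in pool.genes:
                g_hot = truth.immunogenic[(pool.patient_id, gene)]
                g_rate = pc.background_rate + (
                    pc.immunogenic_rate if g_hot else 0.0)
                for cytokine in cytokines:
                    add(pool.patient_id, gene, cytokine, g_rate)
    return wells


def make_reference_epitopes(config: SimulationConfig,
                            include: Sequence[str] = ()) -> list[str]:
    """Seeded random 9--10-mers, optionally prepending exact copies of
    chosen candidate peptides so foreignness has known high scorers."""
    rng = substream(config.seed, "epitopes")
    epitopes = [p.upper() for p in include]
    for _ in range(config.n_reference_epitopes):
        k = int(rng.integers(9, 11))
        epitopes.append(_random_protein(rng, k))
    return epitopes


def write_cohort(cohort: Cohort, config: SimulationConfig, outdir,
                 pools: Optional[Sequence[PoolSpec]] = None,
                 include_singles: bool = False) -> dict[str, Path]:
    """Write the full fixture set under *outdir*; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": outdir / "proteins.fasta",
        "variants": outdir / "variants.tsv",
        "reference_epitopes": outdir / "reference_epitopes.tsv",
        "truth": outdir / "truth.tsv",
    }
    nio.write_protein_fasta(cohort.proteins, paths["proteins"])
    nio.write_variant_table(cohort.variants, paths["variants"])
    nio.write_reference_epitopes(
        make_reference_epitopes(config), paths["reference_epitopes"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("patient_id\tgene\tis_immunogenic\n")
        for (patient, gene), flag in cohort.truth.immunogenic.items():
            fh.write(f"{patient}\t{gene}\t{int(flag)}\n")
    if pools is not None:
        paths["plates"] = outdir / "plates.csv"
        nio.write_plate_csv(
            simulate_plates(pools, cohort.truth, config,
                            include_singles=include_singles),
            paths["plates"])
    return paths


def read_truth(path) -> GroundTruth:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("patient_id", "gene", "is_immunogenic"):
        if col not in df.columns:
            raise NeoprioError(f"{path}: missing column {col!r}")
    return GroundTruth(immunogenic={
        (r["patient_id"], r["gene"]): bool(int(r["is_immunogenic"]))
        for r in df.to_dict("records")})
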