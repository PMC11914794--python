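"""Readers and writers for every external table/sequence format the
pipeline touches.

The canonical interchange formats are plain TSV/CSV with fixed column
names (documented per reader) plus FASTA for protein sequences. Readers
return validated domain records in file order; any row failing a record
invariant is reported with its 1-based line number. Writers are exact
inverses of the readers so that write-then-read round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pydantic import BaseModel, field_validator, model_validator

from .errors import FormatError
from .hgvs import STANDARD_AA

Genotype = Literal["hom_ref", "het", "hom_alt"]
Cytokine = Literal["IFNg", "IL5"]

#: column order of the canonical variants.tsv
VARIANT_COLUMNS = [
    "patient_id", "chrom", "pos", "ref", "alt", "gene", "hgvs_protein",
    "tumor_dna_depth", "tumor_dna_alt", "normal_dna_depth", "normal_dna_alt",
    "rna_depth", "rna_alt", "tpm", "tumor_genotype",
]

PREDICTION_COLUMNS = ["peptide", "allele", "ic50_nm", "stability_hours"]

PLATE_COLUMNS = [
    "patient_id", "stimulus", "cytokine", "replicate", "spot_count",
    "cells_per_well",
]


class VariantTableRow(BaseModel):
    """One somatic variant with its DNA/RNA read evidence and expression."""

    model_config = {"frozen": True}

    patient_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str
    hgvs_protein: str
    tumor_dna_depth: int
    tumor_dna_alt: int
    normal_dna_depth: int
    normal_dna_alt: int
    rna_depth: int
    rna_alt: int
    tpm: float
    tumor_genotype: Genotype

    @field_validator(
        "pos", "tumor_dna_depth", "tumor_dna_alt", "normal_dna_depth",
        "normal_dna_alt", "rna_depth", "rna_alt",
    )
    @classmethod
    def _non_negative(cls, v: int) -> int:
        if v < 0:
            raise ValueError("count fields must be >= 0")
        return v

    @field_validator("tpm")
    @classmethod
    def _tpm_non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("tpm must be >= 0")
        return v

    @model_validator(mode="after")
    def _invariants(self) -> "VariantTableRow":
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele equals alt_allele")
        for alt, depth, label in (
            (self.tumor_dna_alt, self.tumor_dna_depth, "tumor_dna"),
            (self.normal_dna_alt, self.normal_dna_depth, "normal_dna"),
            (self.rna_alt, self.rna_depth, "rna"),
        ):
            if alt > depth:
                raise ValueError(f"{label}_alt ({alt}) exceeds depth ({depth})")
        return self


class PredictionRow(BaseModel):
    """Predicted binding of one peptide to one HLA class I allele."""

    model_config = {"frozen": True}

    peptide: str
    allele: str
    ic50_nm: float
    stability_hours: Optional[float] = None

    @field_validator("peptide")
    @classmethod
    def _standard_residues(cls, v: str) -> str:
        bad = set(v) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residues {sorted(bad)} in peptide")
        return v

    @field_validator("ic50_nm")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("ic50_nm must be > 0")
        return v

    @field_validator("stability_hours")
    @classmethod
    def _stab_non_negative(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v < 0:
            raise ValueError("stability_hours must be >= 0")
        return v


class PlateWell(BaseModel):
    """One ELISpot/Fluorospot well: a raw spot count for one stimulus."""

    model_config = {"frozen": True}

    patient_id: str
    stimulus: str
    cytokine: Cytokine
    replicate: int
    spot_count: int
    cells_per_well: int

    @field_validator("replicate")
    @classmethod
    def _rep_ge_1(cls, v: int) -> int:
        if v < 1:
            raise ValueError("replicate must be >= 1")
        return v

    @field_validator("spot_count")
    @classmethod
    def _spots_ge_0(cls, v: int) -> int:
        if v < 0:
            raise ValueError("spot_count must be >= 0")
        return v

    @field_validator("cells_per_well")
    @classmethod
    def _cells_positive(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("cells_per_well must be > 0")
        return v


# ---------------------------------------------------------------------------
# tabular readers/writers


def _read_table(path, sep: str, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (expected a header line)")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _row_error(path, line_no: int, exc: Exception) -> FormatError:
    # pydantic messages are verbose; keep the first line of each error
    msg = "; ".join(
        str(e.get("msg", e)) for e in getattr(exc, "errors", lambda: [])()
    ) or str(exc)
    return FormatError(f"{path}: line {line_no}: {msg}")


def read_variant_table(path) -> list[VariantTableRow]:
    """Read the canonical ``variants.tsv`` (columns: VARIANT_COLUMNS)."""
    df = _read_table(path, "\t", VARIANT_COLUMNS)
    rows: list[VariantTableRow] = []
    for i, rec in enumerate(df.to_dict("records")):
        line_no = i + 2  # header is line 1
        try:
            rows.append(VariantTableRow(
                patient_id=rec["patient_id"],
                chrom=rec["chrom"],
                pos=rec["pos"],
                ref_allele=rec["ref"],
                alt_allele=rec["alt"],
                gene=rec["gene"],
                hgvs_protein=rec["hgvs_protein"],
                tumor_dna_depth=rec["tumor_dna_depth"],
                tumor_dna_alt=rec["tumor_dna_alt"],
                normal_dna_depth=rec["normal_dna_depth"],
                normal_dna_alt=rec["normal_dna_alt"],
                rna_depth=rec["rna_depth"],
                rna_alt=rec["rna_alt"],
                tpm=rec["tpm"],
                tumor_genotype=rec["tumor_genotype"],
            ))
        except Exception as exc:  # pydantic ValidationError or int() failure
            raise _row_error(path, line_no, exc) from exc
    return rows


def write_variant_table(rows: Iterable[VariantTableRow], path) -> None:
    records = [
        {
            "patient_id": r.patient_id, "chrom": r.chrom, "pos": r.pos,
            "ref": r.ref_allele, "alt": r.alt_allele, "gene": r.gene,
            "hgvs_protein": r.hgvs_protein,
            "tumor_dna_depth": r.tumor_dna_depth,
            "tumor_dna_alt": r.tumor_dna_alt,
            "normal_dna_depth": r.normal_dna_depth,
            "normal_dna_alt": r.normal_dna_alt,
            "rna_depth": r.rna_depth, "rna_alt": r.rna_alt,
            "tpm": repr(r.tpm), "tumor_genotype": r.tumor_genotype,
        }
        for r in rows
    ]
    pd.DataFrame(records, columns=VARIANT_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_predictions(path) -> list[PredictionRow]:
    """Read ``predictions.tsv``; key (peptide, allele) must be unambiguous."""
    df = _read_table(path, "\t", ["peptide", "allele", "ic50_nm"])
    has_stab = "stability_hours" in df.columns
    rows: list[PredictionRow] = []
    seen: dict[tuple[str, str], PredictionRow] = {}
    for i, rec in enumerate(df.to_dict("records")):
        line_no = i + 2
        stab = rec.get("stability_hours", "") if has_stab else ""
        try:
            row = PredictionRow(
                peptide=rec["peptide"],
                allele=rec["allele"],
                ic50_nm=rec["ic50_nm"],
                stability_hours=None if stab == "" else stab,
            )
        except Exception as exc:
            raise _row_error(path, line_no, exc) from exc
        key = (row.peptide, row.allele)
        if key in seen:
            if seen[key] != row:
                raise FormatError(
                    f"{path}: line {line_no}: conflicting duplicate for "
                    f"peptide {row.peptide} / allele {row.allele}")
            continue  # identical duplicate tolerated
        seen[key] = row
        rows.append(row)
    return rows


def write_predictions(rows: Iterable[PredictionRow], path) -> None:
    records = [
        {
            "peptide": r.peptide, "allele": r.allele,
            "ic50_nm": repr(r.ic50_nm),
            "stability_hours": "" if r.stability_hours is None
            else repr(r.stability_hours),
        }
        for r in rows
    ]
    pd.DataFrame(records, columns=PREDICTION_COLUMNS).to_csv(
        path, sep="\t", index=False)


def predictions_index(rows: Iterable[PredictionRow]) -> dict[tuple[str, str], PredictionRow]:
    """Lookup table keyed by (peptide, allele)."""
    return {(r.peptide, r.allele): r for r in rows}


def read_plate_csv(path) -> list[PlateWell]:
    """Read ``plates.csv`` with one well per row."""
    df = _read_table(path, ",", PLATE_COLUMNS)
    wells: list[PlateWell] = []
    for i, rec in enumerate(df.to_dict("records")):
        line_no = i + 2
        try:
            wells.append(PlateWell(**{k: rec[k] for k in PLATE_COLUMNS}))
        except Exception as exc:
            raise _row_error(path, line_no, exc) from exc
    return wells


def write_plate_csv(wells: Iterable[PlateWell], path) -> None:
    records = [w.model_dump() for w in wells]
    pd.DataFrame(records, columns=PLATE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sequence readers/writers


def read_protein_fasta(path) -> dict[str, str]:
    """Read a protein FASTA into ``{id: uppercase sequence}``.

    Duplicate ids and non-standard residues are fatal: downstream peptide
    design indexes into these sequences by residue position, so silent
    ambiguity is not acceptable.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    proteins: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in proteins:
            raise FormatError(f"{path}: duplicate sequence id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - STANDARD_AA
        if bad:
            raise FormatError(
                f"{path}: record {record.id!r} contains non-amino-acid "
                f"character(s) {sorted(bad)}")
        proteins[record.id] = seq
    return proteins


def write_protein_fasta(proteins: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in proteins.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_epitopes(path) -> list[str]:
    """Read the foreignness reference set: FASTA, or one peptide per line
    (an optional ``peptide`` header line is skipped)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if text.lstrip().startswith(">"):
        return list(read_protein_fasta(path).values())
    peptides = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        pep = line.strip().upper()
        if not pep or (line_no == 1 and pep == "PEPTIDE"):
            continue
        bad = set(pep) - STANDARD_AA
        if bad:
            raise FormatError(
                f"{path}: line {line_no}: non-amino-acid character(s) "
                f"{sorted(bad)}")
        peptides.append(pep)
    return peptides


def write_reference_epitopes(peptides: Iterable[str], path) -> None:
    Path(path).write_text(
        "peptide\n" + "".join(f"{p}\n" for p in peptides), encoding="utf-8")


def read_hla_alleles(path) -> list[str]:
    """Plain-text allele list, one per line (e.g. ``HLA-A*02:01``)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    alleles = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()]
    return [a for a in alleles if a]


# ---------------------------------------------------------------------------
# optional VCF convenience reader (TSV stays the contract)


def read_variant_vcf(path, tumor_sample: str, normal_sample: str,
                     patient_id: Optional[str] = None) -> list[VariantTableRow]:
    """Map an annotated VCF into variant-table rows.

    Expectations: per-sample ``AD``/``DP`` FORMAT fields for the tumor and
    normal DNA samples; a SnpEff-style ``ANN`` INFO field carrying the gene
    (subfield 4) and protein HGVS (subfield 11); optional ``TPM``,
    ``RNA_DP`` and ``RNA_AD`` INFO fields (default 0). This reader is a
    convenience on top of the canonical TSV.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - env-dependent
        raise FormatError("VCF support requires the cyvcf2 package") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in (tumor_sample, normal_sample):
        if s not in samples:
            raise FormatError(f"{path}: sample {s!r} not in VCF ({samples})")
    i_t, i_n = samples.index(tumor_sample), samples.index(normal_sample)
    rows: list[VariantTableRow] = []
    for v in vcf:
        ann = v.INFO.get("ANN")
        if ann is None:
            continue
        fields = str(ann).split(",")[0].split("|")
        gene = fields[3] if len(fields) > 3 else ""
        hgvs_p = fields[10] if len(fields) > 10 else ""
        if not hgvs_p:
            continue
        ad = v.format("AD")
        dp = v.format("DP")
        t_alt = int(ad[i_t][1]) if ad is not None else 0
        n_alt = int(ad[i_n][1]) if ad is not None else 0
        t_dp = int(dp[i_t][0]) if dp is not None else 0
        n_dp = int(dp[i_n][0]) if dp is not None else 0
        gts = v.genotypes[i_t][:2]
        genotype = ("hom_alt" if gts == [1, 1]
                    else "het" if 1 in gts else "hom_ref")
        rows.append(VariantTableRow(
            patient_id=patient_id or tumor_sample,
            chrom=str(v.CHROM), pos=int(v.POS),
            ref_allele=str(v.REF), alt_allele=str(v.ALT[0]),
            gene=gene, hgvs_protein=hgvs_p,
            tumor_dna_depth=t_dp, tumor_dna_alt=t_alt,
            normal_dna_depth=n_dp, normal_dna_alt=n_alt,
            rna_depth=int(v.INFO.get("RNA_DP") or 0),
            rna_alt=int(v.INFO.get("RNA_AD") or 0),
            tpm=float(v.INFO.get("TPM") or 0.0),
            tumor_genotype=genotype,
        ))
    return rows
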