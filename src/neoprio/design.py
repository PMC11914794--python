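"""Peptide design around a missense substitution.

Four candidate classes are produced from a prioritized variant:

- ``ipv_long``: two overlapping 20-mers with the mutant residue at
  peptide positions 6 and 15, chosen to tile the neighbourhood so that
  every class I and most class II epitopes containing the mutation are
  covered. Windows that would run off a protein terminus are shifted
  minimally to fit (``clamped=True``); a protein shorter than 20 residues
  yields the whole protein as a single clamped candidate.
- ``tesla_short``: every 8--12-mer window that contains the mutant
  residue, paired with its wild-type counterpart.
- ``ipv_short``: the top predicted class I binders among the
  mutation-spanning 8--12-mers inside the two ipv_long 20-mers.
- ``tesla_long``: the ipv_long 20-mer whose sequence contains a given
  tesla_short peptide.

All residue positions and peptide offsets are 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import NeoprioError
from .hgvs import parse_protein_hgvs
from .io import VariantTableRow

SHORT_LENGTHS = range(8, 13)
LONG_LENGTH = 20
#: mutant-residue offsets of the two designed 20-mers
LONG_OFFSETS = (6, 15)

#: residues predictors reject; candidates containing them are dropped
_PREDICTOR_HOSTILE = frozenset("UX")


@dataclass(frozen=True)
class ProteinContext:
    """A missense substitution anchored on its wild-type protein."""

    sequence_id: str
    protein: str
    mut_pos: int  # 1-based
    wt_residue: str
    mut_residue: str

    def __post_init__(self):
        if not 1 <= self.mut_pos <= len(self.protein):
            raise NeoprioError(
                f"{self.sequence_id}: mutation position {self.mut_pos} "
                f"outside protein of length {len(self.protein)}")
        if self.protein[self.mut_pos - 1] != self.wt_residue:
            raise NeoprioError(
                f"{self.sequence_id}: reference residue mismatch at "
                f"position {self.mut_pos}: protein has "
                f"{self.protein[self.mut_pos - 1]!r}, annotation says "
                f"{self.wt_residue!r}")
        if self.wt_residue == self.mut_residue:
            raise NeoprioError(
                f"{self.sequence_id}: wild-type and mutant residues are "
                f"identical at position {self.mut_pos}")

    @property
    def mutant_protein(self) -> str:
        i = self.mut_pos - 1
        return self.protein[:i] + self.mut_residue + self.protein[i + 1:]


@dataclass(frozen=True)
class PeptideCandidate:
    """A designed peptide and its wild-type counterpart."""

    sequence: str
    wt_sequence: str
    source_variant: str  # "<patient>:<gene>" or sequence id
    mut_offset: int  # 1-based position of the mutant residue in sequence
    klass: str  # ipv_long | ipv_short | tesla_short | tesla_long
    clamped: bool = False

    def __post_init__(self):
        if len(self.sequence) != len(self.wt_sequence):
            raise NeoprioError("sequence/wt_sequence length mismatch")
        diffs = [i for i, (a, b) in
                 enumerate(zip(self.sequence, self.wt_sequence)) if a != b]
        if diffs != [self.mut_offset - 1]:
            raise NeoprioError(
                f"candidate must differ from wild type exactly at "
                f"mut_offset {self.mut_offset}; differs at "
                f"{[d + 1 for d in diffs]}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def context_from_hgvs(sequence_id: str, protein: str,
                      hgvs_protein: str) -> ProteinContext:
    """Build a :class:`ProteinContext` from a protein and its HGVS
    annotation, verifying the annotated wild-type residue."""
    sub = parse_protein_hgvs(hgvs_protein)
    if sub.pos > len(protein):
        raise NeoprioError(
            f"{sequence_id}: HGVS position {sub.pos} beyond protein "
            f"length {len(protein)}")
    return ProteinContext(
        sequence_id=sequence_id, protein=protein.upper(),
        mut_pos=sub.pos, wt_residue=sub.wt, mut_residue=sub.mut)


def context_for_variant(row: VariantTableRow,
                        proteins: dict[str, str]) -> ProteinContext:
    if row.gene not in proteins:
        raise NeoprioError(
            f"no protein sequence for gene {row.gene!r} "
            f"(variant {row.patient_id} {row.chrom}:{row.pos})")
    return context_from_hgvs(row.gene, proteins[row.gene], row.hgvs_protein)


def _window_candidate(ctx: ProteinContext, start: int, length: int,
                      klass: str, source: str,
                      clamped: bool = False) -> PeptideCandidate | None:
    """Candidate for the 1-based window [start, start+length-1]; ``None``
    if it contains residues predictors cannot score."""
    end = start + length - 1
    wt = ctx.protein[start - 1:end]
    mut = ctx.mutant_protein[start - 1:end]
    if set(wt) & _PREDICTOR_HOSTILE:
        warnings.warn(
            f"{ctx.sequence_id}: dropped window {start}-{end} containing "
            f"ambiguous residue(s)")
        return None
    return PeptideCandidate(
        sequence=mut, wt_sequence=wt, source_variant=source,
        mut_offset=ctx.mut_pos - start + 1, klass=klass, clamped=clamped)


def design_ipv_long(ctx: ProteinContext,
                    source: str | None = None) -> list[PeptideCandidate]:
    """The one or two overlapping 20-mer candidates for a variant."""
    source = source or ctx.sequence_id
    n = len(ctx.protein)
    if n < LONG_LENGTH:
        cand = _window_candidate(ctx, 1, n, "ipv_long", source, clamped=True)
        return [cand] if cand else []
    out: list[PeptideCandidate] = []
    seen_starts: set[int] = set()
    for offset in LONG_OFFSETS:
        start = ctx.mut_pos - offset + 1
        clamped = False
        if start < 1:
            start, clamped = 1, True
        if start + LONG_LENGTH - 1 > n:
            start, clamped = n - LONG_LENGTH + 1, True
        if start in seen_starts:
            continue
        seen_starts.add(start)
        cand = _window_candidate(ctx, start, LONG_LENGTH, "ipv_long",
                                 source, clamped=clamped)
        if cand:
            out.append(cand)
    return out


def enumerate_short_spanning(
    ctx: ProteinContext,
    lengths: Iterable[int] = SHORT_LENGTHS,
    source: str | None = None,
    klass: str = "tesla_short",
) -> list[PeptideCandidate]:
    """Every k-mer window (k in *lengths*) containing the mutant residue,
    ordered by length ascending then start ascending."""
    source = source or ctx.sequence_id
    n = len(ctx.protein)
    lengths = sorted(set(lengths))
    if n < min(lengths, default=8):
        warnings.warn(
            f"{ctx.sequence_id}: protein length {n} shorter than the "
            f"smallest window; no short peptides generated")
        return []
    out: list[PeptideCandidate] = []
    for k in lengths:
        if k > n:
            continue
        lo = max(1, ctx.mut_pos - k + 1)
        hi = min(n - k + 1, ctx.mut_pos)
        for start in range(lo, hi + 1):
            cand = _window_candidate(ctx, start, k, klass, source)
            if cand:
                out.append(cand)
    return out


def select_ipv_short(long_peptides: Sequence[PeptideCandidate],
                     alleles: Sequence[str], predictor,
                     n: int = 10) -> list[PeptideCandidate]:
    """Top *n* predicted binders among the mutation-spanning 8--12-mers
    inside the given 20-mers.

    Each unique short sequence is scored by its best (minimum) IC50 across
    the patient's alleles; candidates are returned by ascending IC50 with
    ties broken by (length ascending, alphabetical).
    """
    if not alleles:
        raise NeoprioError("select_ipv_short requires at least one allele")
    by_seq: dict[str, PeptideCandidate] = {}
    for long_pep in long_peptides:
        for k in SHORT_LENGTHS:
            if k > long_pep.length:
                continue
            lo = max(1, long_pep.mut_offset - k + 1)
            hi = min(long_pep.length - k + 1, long_pep.mut_offset)
            for start in range(lo, hi + 1):
                seq = long_pep.sequence[start - 1:start + k - 1]
                if seq in by_seq:
                    continue
                by_seq[seq] = PeptideCandidate(
                    sequence=seq,
                    wt_sequence=long_pep.wt_sequence[start - 1:start + k - 1],
                    source_variant=long_pep.source_variant,
                    mut_offset=long_pep.mut_offset - start + 1,
                    klass="ipv_short", clamped=long_pep.clamped)
    scored = []
    for seq, cand in by_seq.items():
        ic50 = min(predictor.predict(seq, a).ic50_nm for a in alleles)
        scored.append((ic50, len(seq), seq, cand))
    scored.sort(key=lambda t: t[:3])
    return [cand for _, _, _, cand in scored[:n]]


def lengthen_tesla(short: PeptideCandidate,
                   ipv_longs: Sequence[PeptideCandidate]) -> PeptideCandidate:
    """The ipv_long 20-mer of the same variant containing *short*.

    When both 20-mers contain the short sequence, the one whose mutant
    residue sits most centrally within the short peptide's span is chosen;
    a tie goes to the offset-6 design (the first emitted).
    """
    if short.klass != "tesla_short":
        raise NeoprioError(f"expected a tesla_short candidate, got {short.klass}")
    containing = []
    for idx, long_pep in enumerate(ipv_longs):
        if long_pep.source_variant != short.source_variant:
            continue
        at = long_pep.sequence.find(short.sequence)
        if at < 0:
            continue
        span_center = at + (len(short.sequence) + 1) / 2  # 1-based midpoint
        centrality = abs(long_pep.mut_offset - span_center)
        containing.append((centrality, idx, long_pep))
    if not containing:
        raise NeoprioError(
            f"no 20-mer of variant {short.source_variant} contains "
            f"{short.sequence}")
    containing.sort(key=lambda t: (t[0], t[1]))
    chosen = containing[0][2]
    return PeptideCandidate(
        sequence=chosen.sequence, wt_sequence=chosen.wt_sequence,
        source_variant=chosen.source_variant, mut_offset=chosen.mut_offset,
        klass="tesla_long", clamped=chosen.clamped)
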