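"""Class-I threshold metrics for 8--12-mer neoepitope candidates.

Five per-candidate metrics are computed and thresholded, all strictly:

- best predicted binding affinity across the patient's alleles, IC50 < 68 nM
- predicted binding stability on that allele, > 1.7 h
- source-gene abundance, > 10 TPM
- agretopicity (mutant IC50 / wild-type IC50 on the same allele), < 0.1
- foreignness, > 1e-16

Foreignness follows the TCR recognition-probability model: each candidate
is aligned gaplessly against a set of reference immunogenic epitopes with
BLOSUM62 scores, the alignment scores are passed through a logistic sum

    S = sum_e exp(-k * (a - s_e)),    R = S / (1 + S)

with displacement ``a`` (default 26) and steepness ``k`` (default 4.87),
so R is in [0, 1) and grows with similarity to any known epitope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.special import expit, logsumexp

from .design import PeptideCandidate
from .errors import MissingPredictionError, NeoprioError
from .hgvs import STANDARD_AA
from .io import PredictionRow

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

# default strict thresholds
IC50_MAX_NM = 68.0
STABILITY_MIN_HOURS = 1.7
TPM_MIN = 10.0
AGRETOPICITY_MAX = 0.1
FOREIGNNESS_MIN = 1e-16


class Predictor(Protocol):
    def predict(self, peptide: str, allele: str) -> PredictionRow: ...


@dataclass(frozen=True)
class ForeignnessParams:
    """Parameters of the recognition-probability curve."""

    midpoint_a: float = 26.0
    steepness_k: float = 4.87
    substitution_matrix: object = field(default_factory=lambda: _BLOSUM62)

    def __post_init__(self):
        if not self.steepness_k > 0:
            raise NeoprioError("steepness_k must be > 0")


@dataclass(frozen=True)
class TeslaThresholds:
    ic50_max_nm: float = IC50_MAX_NM
    stability_min_hours: float = STABILITY_MIN_HOURS
    tpm_min: float = TPM_MIN
    agretopicity_max: float = AGRETOPICITY_MAX
    foreignness_min: float = FOREIGNNESS_MIN


@dataclass
class TeslaMetrics:
    """Per-candidate metric values plus pass/fail flags."""

    peptide: PeptideCandidate
    best_ic50_nm: float
    best_allele: str
    stability_hours: Optional[float]
    tpm: float
    agretopicity: float
    foreignness: float
    c_affinity: bool = False
    c_stability: bool = False
    c_tpm: bool = False
    c_agretopicity: bool = False
    c_foreignness: bool = False
    stability_missing: bool = False
    rank: Optional[int] = None

    @property
    def overall_pass(self) -> bool:
        return (self.c_affinity and self.c_stability and self.c_tpm
                and self.c_agretopicity and self.c_foreignness)


def best_binding(peptide: str, alleles: Sequence[str],
                 predictor: Predictor) -> tuple[float, str, Optional[float]]:
    """Minimum IC50 across *alleles*; stability is read from the same
    allele that provided the minimum."""
    if not alleles:
        raise NeoprioError("best_binding requires a non-empty allele list")
    best: tuple[float, str, Optional[float]] | None = None
    for allele in alleles:
        row = predictor.predict(peptide, allele)
        if best is None or row.ic50_nm < best[0]:
            best = (row.ic50_nm, allele, row.stability_hours)
    assert best is not None
    return best


def agretopicity(mut_ic50_nm: float, wt_ic50_nm: float) -> float:
    """Ratio of mutant to wild-type predicted affinity (same allele)."""
    if not mut_ic50_nm > 0 or not wt_ic50_nm > 0:
        raise NeoprioError("agretopicity requires positive IC50 values")
    return mut_ic50_nm / wt_ic50_nm


def _checked(seq: str, label: str) -> str:
    bad = set(seq) - STANDARD_AA
    if bad:
        raise NeoprioError(f"non-standard residue(s) {sorted(bad)} in {label}")
    return seq


def alignment_score(peptide: str, epitope: str, matrix=None) -> int:
    """Best gapless local alignment score between two peptides.

    Maximum over all relative offsets of the best contiguous run of
    per-position substitution scores (Kadane), floored at 0. Equivalent to
    ungapped Smith-Waterman.
    """
    matrix = _BLOSUM62 if matrix is None else matrix
    a = _checked(peptide.upper(), "peptide")
    b = _checked(epitope.upper(), "epitope")
    if not a or not b:
        raise NeoprioError("alignment_score requires non-empty sequences")
    best = 0
    for shift in range(-(len(b) - 1), len(a)):
        run = 0
        for i in range(max(0, shift), min(len(a), shift + len(b))):
            run = max(0, run) + matrix[a[i], b[i - shift]]
            best = max(best, run)
    return int(best)


def foreignness(peptide: str, reference_epitopes: Sequence[str],
                params: ForeignnessParams | None = None) -> float:
    """Recognition probability R = S/(1+S) against the reference set.

    Computed in log space (logsumexp + logistic) so that near-identical
    matches with large alignment scores do not overflow; an empty
    reference set gives exactly 0.
    """
    params = params or ForeignnessParams()
    if not reference_epitopes:
        return 0.0
    scores = np.array([
        alignment_score(peptide, e, params.substitution_matrix)
        for e in reference_epitopes
    ], dtype=float)
    log_s = logsumexp(params.steepness_k * (scores - params.midpoint_a))
    r = float(expit(log_s))
    # contract: R < 1 even when the logistic saturates in float arithmetic
    return min(r, np.nextafter(1.0, 0.0))


def tesla_filter(metrics: TeslaMetrics,
                 thresholds: TeslaThresholds | None = None) -> TeslaMetrics:
    """Apply the five strict threshold comparisons, setting flags in place.

    A candidate with no stability prediction fails the stability criterion
    and is marked ``stability_missing`` rather than passing silently.
    """
    t = thresholds or TeslaThresholds()
    metrics.c_affinity = metrics.best_ic50_nm < t.ic50_max_nm
    if metrics.stability_hours is None:
        metrics.c_stability = False
        metrics.stability_missing = True
    else:
        metrics.c_stability = metrics.stability_hours > t.stability_min_hours
        metrics.stability_missing = False
    metrics.c_tpm = metrics.tpm > t.tpm_min
    metrics.c_agretopicity = metrics.agretopicity < t.agretopicity_max
    metrics.c_foreignness = metrics.foreignness > t.foreignness_min
    return metrics


def compute_tesla_metrics(
    candidate: PeptideCandidate,
    alleles: Sequence[str],
    predictor: Predictor,
    tpm: float,
    reference_epitopes: Sequence[str],
    params: ForeignnessParams | None = None,
    thresholds: TeslaThresholds | None = None,
) -> TeslaMetrics:
    """Score one mutation-spanning short candidate end to end.

    The wild-type counterpart is scored on the mutant's best allele so
    agretopicity compares presentation of the two ligands on the same HLA
    molecule.
    """
    ic50, allele, stability = best_binding(candidate.sequence, alleles,
                                           predictor)
    wt_ic50 = predictor.predict(candidate.wt_sequence, allele).ic50_nm
    metrics = TeslaMetrics(
        peptide=candidate,
        best_ic50_nm=ic50,
        best_allele=allele,
        stability_hours=stability,
        tpm=tpm,
        agretopicity=agretopicity(ic50, wt_ic50),
        foreignness=foreignness(candidate.sequence, reference_epitopes,
                                params),
    )
    return tesla_filter(metrics, thresholds)


def tesla_rank(passing: Sequence[TeslaMetrics]) -> list[TeslaMetrics]:
    """Order candidates by ascending best IC50; ties by descending
    foreignness, then alphabetical sequence. Rank is written back."""
    ordered = sorted(
        passing,
        key=lambda m: (m.best_ic50_nm, -m.foreignness, m.peptide.sequence))
    for rank, m in enumerate(ordered, start=1):
        m.rank = rank
    return ordered


# ---------------------------------------------------------------------------
# predictors


class TablePredictor:
    """Predictor backed by a precomputed predictions table."""

    def __init__(self, rows: Sequence[PredictionRow]):
        self._index = {(r.peptide, r.allele): r for r in rows}

    def predict(self, peptide: str, allele: str) -> PredictionRow:
        try:
            return self._index[(peptide, allele)]
        except KeyError:
            raise MissingPredictionError(
                f"no prediction for peptide {peptide!r} / allele {allele!r}"
            ) from None


def _fnv1a64(data: bytes) -> int:
    h = 0xCBF29CE484222325
    for byte in data:
        h = ((h ^ byte) * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    return h


class MockPredictor:
    """Deterministic, platform-independent stand-in predictor.

    IC50 is log-uniform in [1, 50000) nM and stability uniform in
    [0.1, 10) h, both derived from an FNV-1a hash of
    ``"<seed>|<peptide>|<allele>"`` so identical inputs always give
    identical outputs on any platform.
    """

    IC50_RANGE = (1.0, 50000.0)
    STABILITY_RANGE = (0.1, 10.0)

    def __init__(self, seed: int = 0):
        self.seed = int(seed)

    def _uniform(self, key: str) -> float:
        return _fnv1a64(key.encode("utf-8")) / 2.0 ** 64

    def predict(self, peptide: str, allele: str) -> PredictionRow:
        _checked(peptide, "peptide")
        base = f"{self.seed}|{peptide}|{allele}"
        lo, hi = self.IC50_RANGE
        u = self._uniform(base)
        ic50 = float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
        s_lo, s_hi = self.STABILITY_RANGE
        stab = s_lo + self._uniform(base + "|stability") * (s_hi - s_lo)
        return PredictionRow(peptide=peptide, allele=allele,
                             ic50_nm=ic50, stability_hours=stab)
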