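"""ELISpot/Fluorospot screen analysis.

Raw spot counts are averaged over replicate wells, converted to
spot-forming cells (SFC) per 10^6 PBMC, background-subtracted against the
patient's pooled negative-control wells (culture media and DMSO), and
called positive when the net signal strictly exceeds a threshold
(default 100 SFC / 10^6 PBMC).

PHA wells are positive controls: a PHA condition that does not itself
exceed the threshold marks every call of that (patient, cytokine) group
with ``qc_flag="QC-warn"``; data are flagged, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import MissingControlError, NeoprioError
from .io import PlateWell

POSITIVITY_THRESHOLD = 100.0
NEGATIVE_CONTROLS = ("media", "DMSO")
POSITIVE_CONTROL = "PHA"


@dataclass(frozen=True)
class ScreenCall:
    """Normalized, background-subtracted result for one stimulus."""

    patient_id: str
    stimulus: str
    cytokine: str
    mean_raw_spots: float
    sfc_per_million: float
    background_sfc: float
    positive: bool
    qc_flag: str = ""

    @property
    def net_sfc(self) -> float:
        return self.sfc_per_million - self.background_sfc


@dataclass(frozen=True)
class PoolSummary:
    n_tested: int
    n_positive: int

    @property
    def n_negative(self) -> int:
        return self.n_tested - self.n_positive

    @property
    def percent_positive(self) -> float:
        return 100.0 * self.n_positive / self.n_tested


@dataclass
class CohortSummary:
    """Per-(pool, cytokine) positivity counts across a cohort."""

    pools: dict[tuple[str, str], PoolSummary] = field(default_factory=dict)

    def get(self, pool: str, cytokine: str) -> PoolSummary:
        return self.pools[(pool, cytokine)]


def sfc_per_million(raw_count: float, cells_per_well: int) -> float:
    """Scale a raw spot count to SFC per 10^6 cells."""
    if cells_per_well <= 0:
        raise NeoprioError("cells_per_well must be > 0")
    return raw_count * (1_000_000 / cells_per_well)


def summarize_condition(wells: Sequence[PlateWell]) -> float:
    """Mean raw spot count over replicate wells of one condition."""
    if not wells:
        raise NeoprioError("summarize_condition requires at least one well")
    keys = {(w.patient_id, w.stimulus, w.cytokine) for w in wells}
    if len(keys) > 1:
        raise NeoprioError(
            f"wells from more than one condition: {sorted(keys)}")
    return sum(w.spot_count for w in wells) / len(wells)


def call_positive(patient_id: str, stimulus: str, cytokine: str,
                  mean_raw_spots: float, stim_sfc: float,
                  background_sfc: float,
                  threshold: float = POSITIVITY_THRESHOLD,
                  qc_flag: str = "") -> ScreenCall:
    """Background-subtract and apply the strict positivity threshold.

    Negative net values are kept as computed (not clipped at zero); they
    are simply negative calls.
    """
    net = stim_sfc - background_sfc
    return ScreenCall(
        patient_id=patient_id, stimulus=stimulus, cytokine=cytokine,
        mean_raw_spots=mean_raw_spots, sfc_per_million=stim_sfc,
        background_sfc=background_sfc, positive=net > threshold,
        qc_flag=qc_flag)


def _group_wells(wells: Iterable[PlateWell]):
    groups: dict[tuple[str, str], dict[str, list[PlateWell]]] = {}
    for w in wells:
        groups.setdefault((w.patient_id, w.cytokine), {}) \
              .setdefault(w.stimulus, []).append(w)
    return groups


def analyze_plates(wells: Sequence[PlateWell],
                   threshold: float = POSITIVITY_THRESHOLD) -> list[ScreenCall]:
    """Full plate analysis: one call per (patient, stimulus, cytokine).

    Background is the pooled mean SFC of all media and DMSO wells of the
    same patient/cytokine; a missing negative control is fatal. Control
    wells themselves produce no calls.
    """
    calls: list[ScreenCall] = []
    for (patient, cytokine), by_stim in _group_wells(wells).items():
        neg_wells = [w for name in NEGATIVE_CONTROLS
                     for w in by_stim.get(name, [])]
        if not neg_wells:
            raise MissingControlError(
                f"no negative-control (media/DMSO) wells for patient "
                f"{patient}, cytokine {cytokine}")
        background = sum(
            sfc_per_million(w.spot_count, w.cells_per_well)
            for w in neg_wells) / len(neg_wells)

        qc_flag = ""
        if POSITIVE_CONTROL in by_stim:
            pha = by_stim[POSITIVE_CONTROL]
            pha_sfc = sfc_per_million(summarize_condition(pha),
                                      pha[0].cells_per_well)
            if not pha_sfc - background > threshold:
                qc_flag = "QC-warn"

        for stimulus, stim_wells in by_stim.items():
            if stimulus in NEGATIVE_CONTROLS or stimulus == POSITIVE_CONTROL:
                continue
            mean_raw = summarize_condition(stim_wells)
            stim_sfc = sfc_per_million(mean_raw,
                                       stim_wells[0].cells_per_well)
            calls.append(call_positive(
                patient, stimulus, cytokine, mean_raw, stim_sfc,
                background, threshold, qc_flag))
    return calls


def summarize_cohort(calls: Sequence[ScreenCall],
                     pool_labels: Optional[Sequence[str]] = None
                     ) -> CohortSummary:
    """Count positive/negative calls per (pool stimulus, cytokine).

    *pool_labels* restricts the summary to the named stimuli (e.g. the
    four pool classes); by default every stimulus present is summarized.
    Calls are expected to be unique per (patient, stimulus, cytokine).
    """
    keys = {(c.patient_id, c.stimulus, c.cytokine) for c in calls}
    if len(keys) != len(calls):
        raise NeoprioError(
            "duplicate (patient, stimulus, cytokine) calls; deduplicate "
            "before summarizing")
    summary = CohortSummary()
    counts: dict[tuple[str, str], list[int]] = {}
    for c in calls:
        if pool_labels is not None and c.stimulus not in pool_labels:
            continue
        tested_pos = counts.setdefault((c.stimulus, c.cytokine), [0, 0])
        tested_pos[0] += 1
        tested_pos[1] += int(c.positive)
    for key, (tested, pos) in counts.items():
        summary.pools[key] = PoolSummary(n_tested=tested, n_positive=pos)
    return summary


def deconvolute(pool_call: ScreenCall,
                variant_calls: Sequence[ScreenCall]) -> list[ScreenCall]:
    """Attribute a positive pool response to its member stimuli.

    Returns the individually positive variant calls; an empty list is a
    valid outcome (no single member reproduces the pool response on its
    own).
    """
    if not pool_call.positive:
        raise NeoprioError(
            f"deconvolution requires a positive pool call "
            f"({pool_call.stimulus} is negative)")
    mismatched = [
        c for c in variant_calls
        if c.patient_id != pool_call.patient_id
        or c.cytokine != pool_call.cytokine]
    if mismatched:
        raise NeoprioError(
            "variant calls must share the pool call's patient and cytokine")
    return [c for c in variant_calls if c.positive]
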