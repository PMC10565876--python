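"""Orchestration of the pulse-SILAC substrate calls.

Stages, in order:

1. a null (control-line vs control-line) contrast defines the *background*
   set — proteins that drift regardless of bait induction;
2. the main bait-vs-control contrast on light intensities at the late
   timepoint yields candidates after background subtraction;
3. an optional late-vs-early timepoint contrast within the bait condition
   confirms that candidate abundance keeps decreasing;
4. an optional label-free (LFQ) contrast under a cullin inhibitor checks
   whether a candidate's abundance is rescued when the ligase is off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .differential import (
    DEFAULT_LOG2_FC_CUT,
    DEFAULT_RAW_P_CUT,
    DifferentialResult,
)
from .io_formats import ExperimentDesign, IntensityTable

__all__ = [
    "DegradomeCall",
    "background_set",
    "call_substrates_16h",
    "confirm_timepoint",
    "mln_rescue",
]

CANDIDATE = "candidate"
CONFIRMED = "confirmed"
REJECTED_BACKGROUND = "rejected_background"
NOT_CANDIDATE = "not_candidate"

MLN_RESCUED = "rescued"
MLN_NOT_RESCUED = "not_rescued"
MLN_NOT_DETECTED = "not_detected"


@dataclass
class DegradomeCall:
    """Per-protein stage flags and final status for one bait."""

    protein: str
    bait: str
    decreased_16h: bool = False
    in_background: bool = False
    confirmed_timepoint: Optional[bool] = None
    rescued_by_mln: Optional[bool] = None
    mln_status: Optional[str] = None
    final_status: str = NOT_CANDIDATE


def background_set(
    null_results: list[DifferentialResult],
    log2_fc_cut: float = DEFAULT_LOG2_FC_CUT,
    raw_p_cut: float = DEFAULT_RAW_P_CUT,
) -> frozenset[str]:
    """Proteins drifting in the null contrast: log2 FC <= cut and
    raw p <= cut.  Computed once per batch, applied to every bait."""
    return frozenset(
        r.protein
        for r in null_results
        if r.log2_fc <= log2_fc_cut and r.raw_p <= raw_p_cut
    )


def call_substrates_16h(
    bait_results: list[DifferentialResult],
    background: frozenset[str],
    bait: str = "",
) -> dict[str, DegradomeCall]:
    """Initial calls from the late-timepoint bait-vs-control contrast."""
    calls: dict[str, DegradomeCall] = {}
    for r in bait_results:
        call = DegradomeCall(protein=r.protein, bait=bait)
        call.decreased_16h = bool(r.is_candidate)
        call.in_background = r.protein in background
        if not call.decreased_16h:
            call.final_status = NOT_CANDIDATE
        elif call.in_background:
            call.final_status = REJECTED_BACKGROUND
        else:
            call.final_status = CANDIDATE
        calls[r.protein] = call
    return calls


def confirm_timepoint(
    calls: dict[str, DegradomeCall],
    results_late_vs_early: list[DifferentialResult],
) -> dict[str, DegradomeCall]:
    """Upgrade candidates that are also candidates in the late-vs-early
    contrast within the bait condition.  Non-candidates keep their flag
    unset (they are never tested)."""
    by_protein = {r.protein: r for r in results_late_vs_early}
    for protein, call in calls.items():
        if call.final_status != CANDIDATE:
            continue
        r = by_protein.get(protein)
        confirmed = bool(r is not None and r.is_candidate)
        call.confirmed_timepoint = confirmed
        if confirmed:
            call.final_status = CONFIRMED
    return calls


def mln_rescue(
    lfq_table: IntensityTable,
    design: ExperimentDesign,
    calls: dict[str, DegradomeCall],
    inhibitor_condition: str,
    vehicle_condition: str,
) -> dict[str, DegradomeCall]:
    """Directional LFQ comparison under cullin inhibition.

    ``rescued_by_mln`` is true when the candidate's mean log2 LFQ under the
    inhibitor strictly exceeds the vehicle mean.  Candidates absent from
    the table (or unobserved in both conditions) are reported as not
    detected, never raised.  The table is expected to have all missing
    values imputed with the minimum-value (DetQuantile, scope='all') mode.
    """
    inh = [s for s in design.samples(condition=inhibitor_condition, channel="lfq")
           if s in lfq_table.samples]
    veh = [s for s in design.samples(condition=vehicle_condition, channel="lfq")
           if s in lfq_table.samples]
    if not inh or not veh:
        raise ConfigurationError(
            "LFQ design must provide samples for both inhibitor and vehicle conditions"
        )
    for protein, call in calls.items():
        if call.final_status not in (CANDIDATE, CONFIRMED):
            continue
        if protein not in lfq_table.proteins:
            call.rescued_by_mln = None
            call.mln_status = MLN_NOT_DETECTED
            continue
        row_inh = lfq_table.values.loc[protein, inh].to_numpy(dtype=float)
        row_veh = lfq_table.values.loc[protein, veh].to_numpy(dtype=float)
        if np.isnan(row_inh).all() and np.isnan(row_veh).all():
            call.rescued_by_mln = None
            call.mln_status = MLN_NOT_DETECTED
            continue
        rescued = bool(np.nanmean(row_inh) > np.nanmean(row_veh))
        call.rescued_by_mln = rescued
        call.mln_status = MLN_RESCUED if rescued else MLN_NOT_RESCUED
    return calls
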