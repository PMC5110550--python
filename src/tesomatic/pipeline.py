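"""End-to-end composition: caller calls -> consensus -> classification ->
somatic calls, plus truth-based evaluation for synthetic cohorts.

A predicted *somatic* insertion is a consensus call that is tissue-specific
within its patient, recurs nowhere else in the cohort (within the merge
window) and matches no population-panel locus — i.e. a private insertion in
the full sense: one patient, one tissue, absent from the reference panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .consensus import ConsensusInsertion, filter_by_support, merge_two_callers
from .frequency import PanelEntry, annotate_frequencies
from .simulate import SyntheticCohort, TruthRecord
from .somatic import CohortSummary, PatientProfile, find_private_insertions, pair_tissues


@dataclass
class CohortCallResult:
    consensus: dict[tuple[str, str], list[ConsensusInsertion]]  # (patient, tissue)
    profiles: list[PatientProfile]
    summary: CohortSummary
    somatic_calls: list[ConsensusInsertion]  # private and panel-absent


def call_cohort(
    cohort: SyntheticCohort,
    window_bp: int | None = None,
    min_reads: int = 5,
    depth_multiplier: float = 4.0,
    apply_support_filter: bool = True,
) -> CohortCallResult:
    """Run consensus calling and somatic classification over a synthetic cohort."""
    cfg = cohort.config
    window = cfg.merge_window if window_bp is None else window_bp
    caller_a, caller_b = cfg.callers

    consensus: dict[tuple[str, str], list[ConsensusInsertion]] = {}
    for patient in cfg.patient_ids:
        for tissue in cfg.tissues:
            merged = merge_two_callers(
                cohort.calls_for(patient, tissue, caller_a),
                cohort.calls_for(patient, tissue, caller_b),
                window_bp=window,
            )
            if apply_support_filter:
                merged = filter_by_support(
                    merged, min_reads=min_reads,
                    depth_multiplier=depth_multiplier, mean_depth=cfg.mean_depth,
                )
            consensus[(patient, tissue)] = merged

    normal_t, tumor_t = cfg.tissues
    profiles = [
        pair_tissues(consensus[(p, normal_t)], consensus[(p, tumor_t)], window_bp=window)
        for p in cfg.patient_ids
    ]
    summary = find_private_insertions(profiles, window_bp=window)
    somatic = panel_filter(summary.private, cohort.panel, window_bp=window)
    return CohortCallResult(consensus, profiles, summary, somatic)


def panel_filter(
    insertions: Sequence[ConsensusInsertion],
    panel: Sequence[PanelEntry],
    window_bp: int = 100,
) -> list[ConsensusInsertion]:
    """Keep insertions with no same-family panel locus within the window."""
    anns = annotate_frequencies(insertions, panel, window_bp=window_bp)
    return [a.insertion for a in anns if a.bin == "private"]


@dataclass
class SomaticEvaluation:
    precision: float
    recall: float
    n_true: int
    n_predicted: int
    n_matched: int


def evaluate_somatic(
    predicted: Sequence[ConsensusInsertion],
    truth: Sequence[TruthRecord],
    window_bp: int = 100,
) -> SomaticEvaluation:
    """Precision/recall of somatic detection against the simulated truth.

    A prediction is a true positive when a somatic truth record of the same
    family lies within the window, in the same patient and tissue.  Truth
    loci are spaced far apart by construction, so window matching here is
    unambiguous.
    """
    som = [t for t in truth if t.origin == "somatic"]
    index: dict[tuple[str, str, str, str], list[int]] = {}
    for t in som:
        patient, tissue = t.carriers[0]
        index.setdefault((t.chrom, t.family, patient, tissue), []).append(t.pos)
    for v in index.values():
        v.sort()

    matched_truth: set[tuple[str, str, str, str, int]] = set()
    n_matched = 0
    for c in predicted:
        key = (c.chrom, c.family, c.sample_id, c.tissue)
        positions = index.get(key, [])
        k = int(np.searchsorted(positions, c.pos))
        hit = None
        for idx in (k - 1, k):
            if 0 <= idx < len(positions) and abs(positions[idx] - c.pos) <= window_bp:
                hit = positions[idx]
                break
        if hit is not None:
            n_matched += 1
            matched_truth.add(key + (hit,))

    precision = n_matched / len(predicted) if predicted else float("nan")
    recall = len(matched_truth) / len(som) if som else float("nan")
    return SomaticEvaluation(
        precision=precision,
        recall=recall,
        n_true=len(som),
        n_predicted=len(predicted),
        n_matched=n_matched,
    )
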