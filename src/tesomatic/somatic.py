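"""Normal/tumor comparison and private-insertion discovery.

For each patient the consensus insertions of the two tissues are matched
against each other with the same ±100 bp window used for caller merging.
Insertions found in both tissues are presumed germline; tissue-specific
insertions are candidate somatic events.  A tissue-specific insertion that
recurs nowhere else in the cohort — no same-family insertion within the
window in any other patient (either tissue) or in the same patient's other
tissue — is called *private*.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import round_half_up
from .consensus import ConsensusInsertion, _match_one_to_one


@dataclass
class PatientProfile:
    """Partition of one patient's insertions into shared / normal-only / tumor-only."""

    patient_id: str
    shared: list[tuple[ConsensusInsertion, ConsensusInsertion]]
    normal_only: list[ConsensusInsertion]
    tumor_only: list[ConsensusInsertion]

    @property
    def n_loci(self) -> int:
        """Distinct loci for this patient (a shared pair counts once)."""
        return len(self.shared) + len(self.normal_only) + len(self.tumor_only)


@dataclass
class CohortSummary:
    """Cohort-level insertion counts.

    ``total_insertions`` counts each patient's loci with shared loci counted
    once per patient; ``unique_insertions`` counts private insertions (one
    patient, one tissue, no cohort recurrence).  Breakdowns are keyed by TE
    family and by tissue.
    """

    total_insertions: int
    unique_insertions: int
    unique_by_family: dict[str, int] = field(default_factory=dict)
    unique_by_tissue: dict[str, int] = field(default_factory=dict)
    unique_by_family_tissue: dict[tuple[str, str], int] = field(default_factory=dict)
    private: list[ConsensusInsertion] = field(default_factory=list)


def pair_tissues(
    normal: Sequence[ConsensusInsertion],
    tumor: Sequence[ConsensusInsertion],
    window_bp: int = 100,
) -> PatientProfile:
    """Match a patient's normal and tumor consensus insertions.

    Same one-to-one window matching as caller merging (same chromosome and
    family, distance <= window_bp, maximum pairs then minimum distance).
    """
    ids = {c.sample_id for c in normal} | {c.sample_id for c in tumor}
    if len(ids) > 1:
        raise ValueError(f"calls from more than one patient: {sorted(ids)}")
    patient_id = next(iter(ids)) if ids else ""

    by_group_n: dict[tuple[str, str], list[ConsensusInsertion]] = defaultdict(list)
    by_group_t: dict[tuple[str, str], list[ConsensusInsertion]] = defaultdict(list)
    for c in normal:
        by_group_n[(c.chrom, c.family)].append(c)
    for c in tumor:
        by_group_t[(c.chrom, c.family)].append(c)

    shared: list[tuple[ConsensusInsertion, ConsensusInsertion]] = []
    matched_n: set[int] = set()
    matched_t: set[int] = set()
    for key in sorted(set(by_group_n) & set(by_group_t)):
        gn, gt = by_group_n[key], by_group_t[key]
        pairs = _match_one_to_one([c.pos for c in gn], [c.pos for c in gt], window_bp)
        for i, j in pairs:
            shared.append((gn[i], gt[j]))
            matched_n.add(id(gn[i]))
            matched_t.add(id(gt[j]))
    shared.sort(key=lambda p: (p[0].chrom, p[0].pos, p[0].family))
    normal_only = [c for c in normal if id(c) not in matched_n]
    tumor_only = [c for c in tumor if id(c) not in matched_t]
    return PatientProfile(patient_id, shared, normal_only, tumor_only)


def find_private_insertions(
    profiles: Sequence[PatientProfile], window_bp: int = 100
) -> CohortSummary:
    """Identify private (single-patient, single-tissue) insertions cohort-wide."""
    if not profiles:
        raise ValueError("need at least one patient profile")

    # index every consensus record by (chrom, family) with its owner
    index: dict[tuple[str, str], list[tuple[int, str, str]]] = defaultdict(list)
    for p in profiles:
        for cn, ct in p.shared:
            index[(cn.chrom, cn.family)].append((cn.pos, p.patient_id, "normal"))
            index[(ct.chrom, ct.family)].append((ct.pos, p.patient_id, "tumor"))
        for c in p.normal_only:
            index[(c.chrom, c.family)].append((c.pos, p.patient_id, "normal"))
        for c in p.tumor_only:
            index[(c.chrom, c.family)].append((c.pos, p.patient_id, "tumor"))
    sorted_index: dict[tuple[str, str], tuple[np.ndarray, list[tuple[str, str]]]] = {}
    for key, entries in index.items():
        entries.sort()
        sorted_index[key] = (
            np.array([e[0] for e in entries], dtype=np.int64),
            [(e[1], e[2]) for e in entries],
        )

    def is_private(c: ConsensusInsertion, patient: str, tissue: str) -> bool:
        pos_arr, owners = sorted_index[(c.chrom, c.family)]
        lo = int(np.searchsorted(pos_arr, c.pos - window_bp, side="left"))
        hi = int(np.searchsorted(pos_arr, c.pos + window_bp, side="right"))
        for k in range(lo, hi):
            op, ot = owners[k]
            if op != patient or ot != tissue:
                return False
        return True

    private: list[ConsensusInsertion] = []
    by_family: dict[str, int] = defaultdict(int)
    by_tissue: dict[str, int] = defaultdict(int)
    by_ft: dict[tuple[str, str], int] = defaultdict(int)
    total = 0
    for p in profiles:
        total += p.n_loci
        for tissue, calls in (("normal", p.normal_only), ("tumor", p.tumor_only)):
            for c in calls:
                if is_private(c, p.patient_id, tissue):
                    private.append(c)
                    by_family[c.family] += 1
                    by_tissue[tissue] += 1
                    by_ft[(c.family, tissue)] += 1
    return CohortSummary(
        total_insertions=total,
        unique_insertions=len(private),
        unique_by_family=dict(by_family),
        unique_by_tissue=dict(by_tissue),
        unique_by_family_tissue=dict(by_ft),
        private=private,
    )


def average_private_per_patient(summary: CohortSummary, n_patients: int) -> int:
    """Unique insertions per patient, rounded to the nearest integer."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    return int(round_half_up(summary.unique_insertions / n_patients))


def shared_fraction(summary: CohortSummary) -> float:
    """Percentage of insertions shared between tissues, one decimal."""
    if summary.total_insertions <= 0:
        raise ValueError("total_insertions must be positive")
    pct = 100.0 * (summary.total_insertions - summary.unique_insertions) / summary.total_insertions
    return round_half_up(pct, 1)


def tumor_excess_ratio(summary: CohortSummary) -> float:
    """Ratio of tumor-private to normal-private insertion counts, one decimal."""
    n = summary.unique_by_tissue.get("normal", 0)
    t = summary.unique_by_tissue.get("tumor", 0)
    if n == 0:
        raise ValueError("no normal-private insertions; ratio undefined")
    return round_half_up(t / n, 1)
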