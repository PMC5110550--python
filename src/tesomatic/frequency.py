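"""Population allele-frequency annotation against a reference panel.

Each insertion is matched to the nearest same-family entry of a panel of
known polymorphic TE insertion loci (emulating the 1000 Genomes Phase 3
release) within the positional window, and binned by the matched allele
frequency: *high* (af >= 0.05), *low* (0 < af < 0.05) or *private* (no
panel match).  Normal-vs-tumor frequency-distribution differences are
tested with a two-sample Kolmogorov–Smirnov test on the matched allele
frequencies (private mapped to 0); a chi-square on the 3x2 bin table is
reported as a companion statistic because a KS test on three discrete bins
alone is degenerate.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConsensusInsertion

BINS = ("private", "low", "high")
HIGH_AF_THRESHOLD = 0.05


@dataclass(frozen=True)
class PanelEntry:
    chrom: str
    pos: int
    family: str
    af: float

    def __post_init__(self) -> None:
        if not 0.0 < self.af <= 1.0:
            raise ValueError(f"panel allele frequency must be in (0, 1], got {self.af}")


@dataclass(frozen=True)
class FrequencyAnnotation:
    insertion: ConsensusInsertion
    matched_panel_entry: PanelEntry | None
    bin: str


@dataclass
class BinComparisonResult:
    statistic: float
    pvalue: float
    bin_counts: pd.DataFrame
    chi2_statistic: float
    chi2_pvalue: float


def _assign_bin(af: float | None, boundary_bin: str) -> str:
    if af is None:
        return "private"
    if af > HIGH_AF_THRESHOLD:
        return "high"
    if af == HIGH_AF_THRESHOLD:
        return boundary_bin
    return "low"


def annotate_frequencies(
    insertions: Sequence[ConsensusInsertion],
    panel: Sequence[PanelEntry],
    window_bp: int = 100,
    boundary_bin: str = "high",
) -> list[FrequencyAnnotation]:
    """Match each insertion to the nearest same-family panel locus.

    ``boundary_bin`` controls where af == 0.05 exactly falls ("high" by
    default, giving a closed upper bin).
    """
    if boundary_bin not in ("high", "low"):
        raise ValueError("boundary_bin must be 'high' or 'low'")
    by_group: dict[tuple[str, str], list[PanelEntry]] = defaultdict(list)
    for e in panel:
        by_group[(e.chrom, e.family)].append(e)
    sorted_panel: dict[tuple[str, str], tuple[np.ndarray, list[PanelEntry]]] = {}
    for key, entries in by_group.items():
        entries.sort(key=lambda e: e.pos)
        sorted_panel[key] = (np.array([e.pos for e in entries], dtype=np.int64), entries)

    out: list[FrequencyAnnotation] = []
    for ins in insertions:
        match: PanelEntry | None = None
        group = sorted_panel.get((ins.chrom, ins.family))
        if group is not None:
            pos_arr, entries = group
            k = int(np.searchsorted(pos_arr, ins.pos))
            best_d = window_bp + 1
            for idx in (k - 1, k):
                if 0 <= idx < len(entries):
                    d = abs(int(pos_arr[idx]) - ins.pos)
                    if d < best_d:
                        best_d = d
                        match = entries[idx]
            if best_d > window_bp:
                match = None
        af = match.af if match is not None else None
        out.append(FrequencyAnnotation(ins, match, _assign_bin(af, boundary_bin)))
    return out


def compare_bin_distributions(
    normal_annotations: Sequence[FrequencyAnnotation],
    tumor_annotations: Sequence[FrequencyAnnotation],
) -> BinComparisonResult:
    """Two-sample KS on matched allele frequencies (private -> 0).

    Also tabulates per-bin counts and a chi-square test on the 3x2 table
    (bins with zero counts in both tissues are dropped from the chi-square).
    """
    if not normal_annotations or not tumor_annotations:
        raise ValueError("both annotation lists must be non-empty")

    def afs(anns: Sequence[FrequencyAnnotation]) -> np.ndarray:
        return np.array(
            [a.matched_panel_entry.af if a.matched_panel_entry else 0.0 for a in anns]
        )

    vn, vt = afs(normal_annotations), afs(tumor_annotations)
    ks = stats.ks_2samp(vn, vt)

    counts = pd.DataFrame(
        {
            "normal": [sum(a.bin == b for a in normal_annotations) for b in BINS],
            "tumor": [sum(a.bin == b for a in tumor_annotations) for b in BINS],
        },
        index=list(BINS),
    )
    nonzero = counts.loc[counts.sum(axis=1) > 0]
    if nonzero.shape[0] >= 2:
        chi2, chi2_p, _, _ = stats.chi2_contingency(nonzero.to_numpy())
    else:  # all mass in one bin for both tissues: no association testable
        chi2, chi2_p = 0.0, 1.0
    return BinComparisonResult(
        statistic=float(ks.statistic),
        pvalue=float(ks.pvalue),
        bin_counts=counts,
        chi2_statistic=float(chi2),
        chi2_pvalue=float(chi2_p),
    )
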