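"""Two-caller consensus insertion calling and read-support filtering.

TE insertion callers that rely on discordant read-pair mapping locate an
insertion only approximately, so two independent callers rarely report
identical coordinates for the same event.  Predictions from the two callers
are therefore treated as the same insertion when they fall within a fixed
window of each other (±100 bp by default), and only insertions supported by
both callers are retained.  A further filter keeps calls whose supporting
read count lies between a fixed minimum (5 reads) and a multiple of the
sample's average sequencing depth (4x by default): the low cutoff removes a
noise mode of weakly supported calls, the high cutoff removes calls in
regions of anomalously deep, ambiguously mapped coverage.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._util import round_half_up

TE_FAMILIES = ("Alu", "L1", "SVA")


@dataclass(frozen=True)
class InsertionCall:
    """A single caller's prediction of a TE insertion point.

    ``pos`` is the 1-based insertion point; callers emit single-bp
    intervals, so the BED representation is (pos-1, pos).
    """

    chrom: str
    pos: int
    family: str
    support_reads: int
    caller_id: str
    sample_id: str
    tissue: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.support_reads < 0:
            raise ValueError("support_reads must be non-negative")


@dataclass(frozen=True)
class ConsensusInsertion:
    """An insertion supported by two distinct callers within the merge window.

    ``pos`` is the rounded midpoint of the contributing calls and
    ``support_reads`` the maximum of their supports: the filter that
    consumes it asks whether sufficient evidence exists anywhere, not for
    an average.
    """

    chrom: str
    pos: int
    family: str
    support_reads: int
    sample_id: str
    tissue: str
    source_calls: tuple[InsertionCall, ...] = field(default=(), compare=False)


def _match_one_to_one(
    pos_a: Sequence[int], pos_b: Sequence[int], window_bp: int
) -> list[tuple[int, int]]:
    """Maximum-cardinality, minimum-total-distance one-to-one matching.

    Pairs index ``i`` of ``pos_a`` with index ``j`` of ``pos_b`` only when
    ``|pos_a[i] - pos_b[j]| <= window_bp``.  Candidate pairs decompose into
    independent connected components (chains of mutually close calls); each
    component is solved exactly with the Hungarian algorithm, using a
    prohibitive pseudo-cost for out-of-window pairs so that maximizing the
    number of real matches dominates minimizing summed distance.
    """
    na, nb = len(pos_a), len(pos_b)
    if na == 0 or nb == 0:
        return []
    a = np.asarray(pos_a, dtype=np.int64)
    b = np.asarray(pos_b, dtype=np.int64)
    order_a = np.argsort(a, kind="stable")
    order_b = np.argsort(b, kind="stable")
    sa, sb = a[order_a], b[order_b]

    # candidate edges via two pointers over the sorted arrays
    edges: list[tuple[int, int]] = []
    lo = 0
    for i in range(na):
        while lo < nb and sb[lo] < sa[i] - window_bp:
            lo += 1
        j = lo
        while j < nb and sb[j] <= sa[i] + window_bp:
            edges.append((i, j))
            j += 1
    if not edges:
        return []

    # union-find over (a-node i) and (b-node na+j)
    parent = list(range(na + nb))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(na + j)
        if ri != rj:
            parent[rj] = ri

    comp_a: dict[int, list[int]] = defaultdict(list)
    comp_b: dict[int, list[int]] = defaultdict(list)
    for i, j in edges:
        r = find(i)
        comp_a[r].append(i)
        comp_b[r].append(j)

    pairs: list[tuple[int, int]] = []
    for root, ai in comp_a.items():
        ai = sorted(set(ai))
        bj = sorted(set(comp_b[root]))
        big = window_bp * (len(ai) + len(bj)) + 1
        cost = np.full((len(ai), len(bj)), big, dtype=np.int64)
        for x, i in enumerate(ai):
            d = np.abs(sb[bj] - sa[i])
            ok = d <= window_bp
            cost[x, ok] = d[ok]
        rows, cols = linear_sum_assignment(cost)
        for x, y in zip(rows, cols):
            if cost[x, y] <= window_bp:
                pairs.append((int(order_a[ai[x]]), int(order_b[bj[y]])))
    return pairs


def _require_uniform_sample(calls: Iterable[InsertionCall], label: str) -> None:
    ids = {(c.sample_id, c.tissue) for c in calls}
    if len(ids) > 1:
        raise ValueError(f"mixed sample_id/tissue in {label} input: {sorted(ids)}")


def merge_two_callers(
    calls_a: Sequence[InsertionCall],
    calls_b: Sequence[InsertionCall],
    window_bp: int = 100,
) -> list[ConsensusInsertion]:
    """Intersect two callers' predictions for one sample.

    Calls match only if same chromosome and family and within ``window_bp``
    (inclusive).  Matching is one-to-one and globally optimal: it maximizes
    the number of matched pairs, breaking ties by minimum summed distance.
    The consensus position is the arithmetic mean of the pair, rounded
    half-up.  Output is sorted by (chrom, pos, family).
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    _require_uniform_sample(calls_a, "caller A")
    _require_uniform_sample(calls_b, "caller B")
    if calls_a and calls_b:
        ka = (calls_a[0].sample_id, calls_a[0].tissue)
        kb = (calls_b[0].sample_id, calls_b[0].tissue)
        if ka != kb:
            raise ValueError(f"caller inputs from different samples: {ka} vs {kb}")

    by_group_a: dict[tuple[str, str], list[InsertionCall]] = defaultdict(list)
    by_group_b: dict[tuple[str, str], list[InsertionCall]] = defaultdict(list)
    for c in calls_a:
        by_group_a[(c.chrom, c.family)].append(c)
    for c in calls_b:
        by_group_b[(c.chrom, c.family)].append(c)

    out: list[ConsensusInsertion] = []
    for key in sorted(set(by_group_a) & set(by_group_b)):
        ga, gb = by_group_a[key], by_group_b[key]
        pairs = _match_one_to_one([c.pos for c in ga], [c.pos for c in gb], window_bp)
        for i, j in pairs:
            ca, cb = ga[i], gb[j]
            pos = int(round_half_up((ca.pos + cb.pos) / 2))
            out.append(
                ConsensusInsertion(
                    chrom=ca.chrom,
                    pos=pos,
                    family=ca.family,
                    support_reads=max(ca.support_reads, cb.support_reads),
                    sample_id=ca.sample_id,
                    tissue=ca.tissue,
                    source_calls=(ca, cb),
                )
            )
    out.sort(key=lambda c: (c.chrom, c.pos, c.family))
    return out


def filter_by_support(
    calls: Sequence[ConsensusInsertion],
    min_reads: int = 5,
    depth_multiplier: float = 4.0,
    mean_depth: float | None = None,
) -> list[ConsensusInsertion]:
    """Keep calls with ``min_reads <= support <= depth_multiplier * mean_depth``.

    Both bounds are inclusive.  Order is preserved.
    """
    if mean_depth is None or mean_depth <= 0:
        raise ValueError("mean_depth must be a positive number")
    upper = depth_multiplier * mean_depth
    return [c for c in calls if min_reads <= c.support_reads <= upper]


def support_histogram(
    calls: Sequence[InsertionCall | ConsensusInsertion], bin_width: int = 1
) -> dict[int, int]:
    """Histogram of supporting-read counts, keyed by bin start.

    With the default synthetic support model this is bimodal: a low mode of
    spurious calls and a high mode near half the sequencing depth.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    counts = Counter((c.support_reads // bin_width) * bin_width for c in calls)
    return dict(sorted(counts.items()))
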