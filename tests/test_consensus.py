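"""Consensus merging and support filtering against brute-force oracles."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tesomatic import filter_by_support, merge_two_callers, support_histogram
from tesomatic.consensus import _match_one_to_one

from conftest import make_call, make_consensus


def oracle_matching(pos_a, pos_b, window):
    """Independent maximum-cardinality minimum-distance matching (networkx)."""
    g = nx.Graph()
    for i, pa in enumerate(pos_a):
        for j, pb in enumerate(pos_b):
            d = abs(pa - pb)
            if d <= window:
                g.add_edge(("a", i), ("b", j), weight=window + 1 - d)
    match = nx.max_weight_matching(g, maxcardinality=True)
    pairs = []
    for u, v in match:
        if u[0] == "b":
            u, v = v, u
        pairs.append((u[1], v[1]))
    return pairs


class TestMergeTwoCallers:
    def test_within_window_merges_at_midpoint(self):
        out = merge_two_callers(
            [make_call(1000)], [make_call(1050, caller="callerB")], window_bp=100
        )
        assert len(out) == 1
        assert out[0].pos == 1025
        assert {c.caller_id for c in out[0].source_calls} == {"callerA", "callerB"}

    def test_midpoint_rounds_half_up(self):
        out = merge_two_callers([make_call(1000)], [make_call(1001, caller="callerB")])
        assert out[0].pos == 1001  # 1000.5 rounds up

    def test_beyond_window_no_merge(self):
        out = merge_two_callers(
            [make_call(1000)], [make_call(1150, caller="callerB")], window_bp=100
        )
        assert out == []

    def test_window_boundary_inclusive(self):
        out = merge_two_callers(
            [make_call(1000)], [make_call(1100, caller="callerB")], window_bp=100
        )
        assert len(out) == 1

    def test_family_mismatch_no_merge(self):
        out = merge_two_callers(
            [make_call(1000, family="Alu")], [make_call(1000, family="L1", caller="callerB")]
        )
        assert out == []

    def test_empty_input(self):
        assert merge_two_callers([], [make_call(5)]) == []
        assert merge_two_callers([], []) == []

    def test_support_is_max_of_pair(self):
        out = merge_two_callers(
            [make_call(1000, support=12)], [make_call(1010, support=30, caller="callerB")]
        )
        assert out[0].support_reads == 30

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError, match="mixed sample_id"):
            merge_two_callers([make_call(10), make_call(500, sample="P2")], [])
        with pytest.raises(ValueError, match="different samples"):
            merge_two_callers([make_call(10)], [make_call(20, sample="P2", caller="callerB")])

    def test_symmetry_of_consensus_loci(self):
        a = [make_call(p) for p in (1000, 1500, 1620, 9000)]
        b = [make_call(p, caller="callerB") for p in (1040, 1580, 1700, 5000)]
        ab = merge_two_callers(a, b)
        ba = merge_two_callers(b, a)
        assert [(c.chrom, c.pos, c.family) for c in ab] == [
            (c.chrom, c.pos, c.family) for c in ba
        ]

    def test_consensus_within_window_of_both_sources(self):
        a = [make_call(p) for p in (100, 260, 400)]
        b = [make_call(p, caller="callerB") for p in (180, 340, 480)]
        for c in merge_two_callers(a, b, window_bp=100):
            ca, cb = c.source_calls
            assert abs(c.pos - ca.pos) <= 100 and abs(c.pos - cb.pos) <= 100

    def test_chained_configuration_finds_maximum_pairs(self):
        # nearest-first greedy would pair (90, 95) only and find 1 pair
        a = [make_call(1000), make_call(1090)]
        b = [make_call(1095, caller="callerB"), make_call(1180, caller="callerB")]
        assert len(merge_two_callers(a, b, window_bp=100)) == 2

    @given(
        pos_a=st.lists(st.integers(1, 2000), max_size=25),
        pos_b=st.lists(st.integers(1, 2000), max_size=25),
        window=st.integers(0, 150),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_optimal_assignment_oracle(self, pos_a, pos_b, window):
        pairs = _match_one_to_one(pos_a, pos_b, window)
        oracle = oracle_matching(pos_a, pos_b, window)
        assert len(pairs) == len(oracle)
        dist = sum(abs(pos_a[i] - pos_b[j]) for i, j in pairs)
        odist = sum(abs(pos_a[i] - pos_b[j]) for i, j in oracle)
        assert dist == odist
        assert len({i for i, _ in pairs}) == len(pairs)  # one-to-one
        assert len({j for _, j in pairs}) == len(pairs)

    @given(
        pos_a=st.lists(st.integers(1, 3000), max_size=15),
        pos_b=st.lists(st.integers(1, 3000), max_size=15),
        w1=st.integers(0, 80),
        w2=st.integers(0, 80),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_widening_window_never_decreases_consensus(self, pos_a, pos_b, w1, w2):
        lo, hi = sorted((w1, w2))
        assert len(_match_one_to_one(pos_a, pos_b, lo)) <= len(
            _match_one_to_one(pos_a, pos_b, hi)
        )


class TestFilterBySupport:
    def test_minimum_boundary(self):
        calls = [make_consensus(100, support=4), make_consensus(700, support=5)]
        kept = filter_by_support(calls, mean_depth=40)
        assert [c.support_reads for c in kept] == [5]

    def test_maximum_boundary_at_4x_depth(self):
        calls = [make_consensus(100, support=160), make_consensus(700, support=161)]
        kept = filter_by_support(calls, mean_depth=40)
        assert [c.support_reads for c in kept] == [160]

    def test_empty_input(self):
        assert filter_by_support([], mean_depth=40) == []

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            filter_by_support([], mean_depth=0)

    def test_raising_min_reads_monotone(self):
        rng = np.random.default_rng(0)
        calls = [make_consensus(1 + 600 * i, support=int(s)) for i, s in enumerate(rng.integers(0, 200, 80))]
        sizes = [len(filter_by_support(calls, min_reads=m, mean_depth=40)) for m in range(0, 30)]
        assert sizes == sorted(sizes, reverse=True)


class TestSupportHistogram:
    def test_unit_bins(self):
        calls = [make_call(1, support=5), make_call(600, support=5), make_call(1200, support=6)]
        assert support_histogram(calls, 1) == {5: 2, 6: 1}

    def test_empty(self):
        assert support_histogram([], 1) == {}

    def test_counts_sum_to_input(self):
        rng = np.random.default_rng(1)
        calls = [make_call(1 + 600 * i, support=int(s)) for i, s in enumerate(rng.integers(0, 99, 57))]
        hist = support_histogram(calls, 10)
        assert sum(hist.values()) == 57

    def test_synthetic_supports_are_bimodal(self, default_cohort):
        """The mixture support model yields separated low and high modes."""
        hist = support_histogram(default_cohort.calls, bin_width=4)
        bins = sorted(hist)
        counts = [hist[b] for b in bins]
        # local maxima over the binned histogram
        peaks = [
            bins[i]
            for i in range(len(counts))
            if (i == 0 or counts[i] >= counts[i - 1])
            and (i == len(counts) - 1 or counts[i] > counts[i + 1])
        ]
        assert any(b < 5 for b in peaks) and any(b >= 10 for b in peaks)
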