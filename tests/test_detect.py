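"""Cycle finding, coverage filtering and the end-to-end detection pipeline."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from dmgraph.detect import (
    coverage_uniform,
    detect_dms,
    find_acyclic_dms,
    find_cyclic_dms,
    shortest_cycle_in_scc,
    strongly_connected_components,
)
from dmgraph.records import (
    Amplicon,
    Breakend,
    DetectParams,
    InsertSizeModel,
    RawCnvCall,
    SVCall,
    ValidationError,
)


def _digraph(edges, n=None, coverages=None):
    """A unit-weight digraph whose vertices carry dummy amplicons."""
    H = nx.DiGraph()
    H.graph["self_junctions"] = {}
    nodes = set(range(n)) if n else {u for e in edges for u in e}
    for v in sorted(nodes):
        cov = coverages[v] if coverages else 10.0
        H.add_node(v, amplicon=Amplicon(v, "chr1", 1000 * v + 100, 1000 * v + 900, cov))
    for u, v in edges:
        H.add_edge(u, v, weight=1)
    return H


class TestSCC:
    def test_directed_cycle_is_one_scc(self):
        H = _digraph([(0, 1), (1, 2), (2, 0)])
        assert strongly_connected_components(H) == [[0, 1, 2]]

    def test_path_gives_singletons(self):
        H = _digraph([(0, 1), (1, 2)])
        assert strongly_connected_components(H) == [[0], [1], [2]]

    def test_empty(self):
        assert strongly_connected_components(nx.DiGraph()) == []


class TestShortestCycle:
    def test_triangle(self):
        H = _digraph([(0, 1), (1, 2), (2, 0)])
        assert shortest_cycle_in_scc(H, [0, 1, 2]) == [0, 1, 2]

    def test_overlapping_three_and_four_cycle(self):
        # 3-cycle 0-1-2 and 4-cycle 0-1-3-4 share edge (0,1)
        H = _digraph([(0, 1), (1, 2), (2, 0), (1, 3), (3, 4), (4, 0)])
        cycle = shortest_cycle_in_scc(H, [0, 1, 2, 3, 4])
        assert cycle == [0, 1, 2]

    def test_singleton_without_self_junction_is_none(self):
        H = _digraph([], n=1)
        assert shortest_cycle_in_scc(H, [0]) is None

    def test_singleton_with_self_junction(self):
        H = _digraph([], n=1)
        H.graph["self_junctions"] = {0: [object()]}
        assert shortest_cycle_in_scc(H, [0]) == [0]

    def test_result_starts_at_smallest_id(self):
        H = _digraph([(5, 3), (3, 7), (7, 5)])
        assert shortest_cycle_in_scc(H, [3, 5, 7]) == [3, 7, 5]


def _brute_force_min_cycle(H):
    """Oracle: minimum directed cycle length by exhaustive enumeration."""
    lengths = [len(c) for c in nx.simple_cycles(H) if len(c) > 1]
    return min(lengths) if lengths else None


def test_shortest_cycle_matches_exhaustive_enumeration():
    """On 200 random digraphs (n <= 8) the SCC-wise shortest cycle equals
    the exhaustive minimum directed-cycle length."""
    rng = random.Random(20210)
    for _ in range(200):
        n = rng.randint(2, 8)
        p = rng.uniform(0.05, 0.5)
        H = _digraph(
            [(u, v) for u in range(n) for v in range(n)
             if u != v and rng.random() < p],
            n=n,
        )
        expected = _brute_force_min_cycle(H)
        found = [
            len(shortest_cycle_in_scc(H, scc))
            for scc in strongly_connected_components(H)
            if len(scc) > 1
        ]
        assert (min(found) if found else None) == expected


class TestCoverageUniform:
    @pytest.mark.parametrize(
        "covs,expected",
        [([10, 12, 11], True), ([5, 30, 10], False), ([7.5], True)],
    )
    def test_examples(self, covs, expected):
        amps = [Amplicon(i, "chr1", 0, 10, c) for i, c in enumerate(covs)]
        assert coverage_uniform(amps) is expected

    def test_missing_coverage_raises(self):
        amps = [Amplicon(0, "chr1", 0, 10, None)]
        with pytest.raises(ValidationError):
            coverage_uniform(amps)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.1, 1e4), min_size=1, max_size=12),
        st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, covs, c):
        amps = [Amplicon(i, "chr1", 0, 10, v) for i, v in enumerate(covs)]
        scaled = [Amplicon(i, "chr1", 0, 10, v * c) for i, v in enumerate(covs)]
        assert coverage_uniform(amps) == coverage_uniform(scaled)


class TestFindCyclic:
    def test_triangle_uniform(self):
        H = _digraph([(0, 1), (1, 2), (2, 0)])
        (pred,) = find_cyclic_dms(H, DetectParams(min_amplicons=3))
        assert pred.cyclic and pred.amplicon_ids == [0, 1, 2]
        assert len(pred.junctions) == 3

    def test_min_amplicons_threshold(self):
        H = _digraph([(0, 1), (1, 2), (2, 0)])
        assert find_cyclic_dms(H, DetectParams(min_amplicons=7)) == []

    def test_coverage_filter_rejects(self):
        H = _digraph([(0, 1), (1, 2), (2, 0)], coverages={0: 5.0, 1: 30.0, 2: 10.0})
        assert find_cyclic_dms(H, DetectParams(min_amplicons=3)) == []
        preds = find_cyclic_dms(
            H, DetectParams(min_amplicons=3, coverage_filter=False)
        )
        assert len(preds) == 1


class TestFindAcyclic:
    def test_long_path_reported_whole(self):
        H = _digraph([(i, i + 1) for i in range(6)])  # 7 vertices
        (pred,) = find_acyclic_dms(H, [], DetectParams(min_amplicons=7))
        assert not pred.cyclic and pred.amplicon_ids == list(range(7))
        assert len(pred.junctions) == 6

    def test_component_with_cyclic_dm_not_rereported(self):
        H = _digraph([(i, (i + 1) % 7) for i in range(7)])
        cyclic = find_cyclic_dms(H, DetectParams(min_amplicons=7))
        assert len(cyclic) == 1
        assert find_acyclic_dms(H, cyclic, DetectParams(min_amplicons=7)) == []

    def test_short_path_below_threshold(self):
        H = _digraph([(0, 1), (1, 2)])
        assert find_acyclic_dms(H, [], DetectParams(min_amplicons=7)) == []


def _chain_inputs(n=10, closing=True, coverage=70.0):
    """n amplicons on one chromosome chained by junctions, optionally closed
    into a circle."""
    calls = [
        RawCnvCall("chr1", i * 1_000_000, i * 1_000_000 + 50_000, coverage)
        for i in range(n)
    ]
    svs = []
    for i in range(n - 1 + (1 if closing else 0)):
        j = (i + 1) % n
        svs.append(
            SVCall.make(
                Breakend("chr1", calls[i].end - 1),
                Breakend("chr1", calls[j].start),
                "DEL" if calls[i].end <= calls[j].start else "ITX",
            )
        )
    return calls, svs


class TestDetectDms:
    def test_no_amplicons_no_predictions(self):
        _, svs = _chain_inputs()
        assert detect_dms([], svs) == []

    def test_closed_chain_is_cyclic_dm(self):
        calls, svs = _chain_inputs(10, closing=True)
        (pred,) = detect_dms(calls, svs)
        assert pred.cyclic and pred.n_amplicons == 10

    def test_open_chain_falls_through_to_acyclic(self):
        calls, svs = _chain_inputs(10, closing=False)
        (pred,) = detect_dms(calls, svs)
        assert not pred.cyclic and pred.n_amplicons == 10

    def test_input_order_invariance(self):
        calls, svs = _chain_inputs(10)
        a = detect_dms(calls, svs)
        b = detect_dms(list(reversed(calls)), list(reversed(svs)))
        assert [(p.cyclic, p.amplicon_ids) for p in a] == [
            (p.cyclic, p.amplicon_ids) for p in b
        ]

    @pytest.mark.parametrize("lower,higher", [(3, 7), (1, 10), (7, 11)])
    def test_monotone_in_min_amplicons(self, lower, higher):
        """Lowering min_amplicons never removes a predicted double minute."""
        calls, svs = _chain_inputs(10)
        strict = detect_dms(calls, svs, params=DetectParams(min_amplicons=higher))
        loose = detect_dms(calls, svs, params=DetectParams(min_amplicons=lower))
        strict_sets = {frozenset(p.amplicon_ids) for p in strict}
        loose_sets = {frozenset(p.amplicon_ids) for p in loose}
        assert strict_sets <= loose_sets

    def test_no_vertex_in_two_predictions(self):
        calls1, svs1 = _chain_inputs(10, closing=True)
        calls2 = [
            RawCnvCall("chr2", i * 1_000_000, i * 1_000_000 + 50_000, 70.0)
            for i in range(8)
        ]
        svs2 = [
            SVCall.make(
                Breakend("chr2", calls2[i].end - 1),
                Breakend("chr2", calls2[i + 1].start),
                "DEL",
            )
            for i in range(7)
        ]
        preds = detect_dms(calls1 + calls2, svs1 + svs2)
        seen = []
        for p in preds:
            seen.extend(p.amplicon_ids)
        assert len(seen) == len(set(seen))
        assert sorted(p.cyclic for p in preds) == [False, True]
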