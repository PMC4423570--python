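"""Amplicon-graph construction.

Merges raw copy-number calls into amplicons, links amplicons whose
boundaries are bridged by SV breakpoint calls into the undirected evidence
graph G, and orients G into the unit-weight auxiliary digraph H by a
deterministic depth-first search.  Cycles of G (candidate double-minute
circles) appear as directed cycles of H.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .records import Amplicon, Breakend, InsertSizeModel, RawCnvCall, SVCall

#: networkx graph attribute keys
EVIDENCE = "evidence"        # list[SVCall] on edges of G
PARENT_EDGE = "parent_edge"  # (u, v) undirected edge of G, on edges of H


def compute_L(model: InsertSizeModel) -> float:
    """Proximity threshold ``L = mean + k * stdev`` in bp.

    A breakend and an amplicon boundary farther apart than L cannot be
    bridged by a concordantly sized read pair and are not considered the
    same junction.
    """
    return model.L


def merge_cnv_calls(calls: Sequence[RawCnvCall], merge_gap: int = 1000) -> List[Amplicon]:
    """Merge nearby same-chromosome copy-number calls into amplicons.

    Calls are sorted by (chrom, start); a run where each successive call
    starts within ``merge_gap`` bp of the merged end so far is unioned.
    Merged coverage is the length-weighted mean of the member coverages
    (weights are the original call lengths).  Ids are assigned densely in
    sorted genomic order.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    ordered = sorted(calls, key=lambda c: (c.chrom, c.start, c.end))
    merged: List[Amplicon] = []
    run: List[RawCnvCall] = []

    def _flush() -> None:
        if not run:
            return
        start = run[0].start
        end = max(c.end for c in run)
        covs = [(c.length, c.coverage) for c in run if c.coverage is not None]
        if len(covs) == len(run) and covs:
            total_len = sum(length for length, _ in covs)
            coverage = sum(length * cov for length, cov in covs) / total_len
        else:
            coverage = None
        merged.append(Amplicon(len(merged), run[0].chrom, start, end, coverage))

    for call in ordered:
        if run and call.chrom == run[0].chrom and call.start <= max(c.end for c in run) + merge_gap:
            run.append(call)
        else:
            _flush()
            run = [call]
    _flush()
    return merged


class _BoundaryIndex:
    """Per-chromosome lookup of the nearest amplicon boundary."""

    def __init__(self, amplicons: Sequence[Amplicon]):
        self._by_chrom: Dict[str, List[Amplicon]] = defaultdict(list)
        for amp in amplicons:
            self._by_chrom[amp.chrom].append(amp)
        for amps in self._by_chrom.values():
            amps.sort(key=lambda a: a.id)

    def match(self, b: Breakend, L: float) -> Optional[int]:
        best: Optional[Tuple[float, int]] = None
        for amp in self._by_chrom.get(b.chrom, ()):
            d = min(abs(b.pos - amp.start), abs(b.pos - (amp.end - 1)))
            if d <= L and (best is None or (d, amp.id) < best):
                best = (d, amp.id)
        return None if best is None else best[1]


def match_breakend(b: Breakend, amplicons: Sequence[Amplicon], L: float) -> Optional[int]:
    """Id of the amplicon whose nearer boundary is closest to ``b``, within L.

    Distance is measured to the nearer of the two interval boundaries
    (positions ``start`` and ``end - 1``), from inside or outside the
    interval: copy-number boundary error is two-sided.  Ties go to the
    smaller amplicon id; returns None when no amplicon on ``b.chrom``
    qualifies.
    """
    return _BoundaryIndex(amplicons).match(b, L)


def build_amplicon_graph(
    amplicons: Sequence[Amplicon],
    svcalls: Sequence[SVCall],
    L: float,
    sv_types: Optional[frozenset] = None,
) -> nx.Graph:
    """Build the undirected amplicon graph G.

    Vertices are amplicon ids (each carrying its :class:`Amplicon` under the
    ``amplicon`` attribute).  For every SV call both breakends are matched
    independently; when they land on two distinct amplicons the edge between
    them gains the call as evidence (parallel evidence collapses onto one
    edge).  A call whose ends match the same amplicon is recorded in the
    graph attribute ``self_junctions`` (a single-segment circle), not as a
    self-loop.  Calls with an unmatched end contribute nothing.  ``sv_types``
    optionally restricts which call types count as evidence.
    """
    G = nx.Graph()
    G.graph["self_junctions"] = defaultdict(list)
    for amp in amplicons:
        G.add_node(amp.id, amplicon=amp)
    index = _BoundaryIndex(amplicons)
    for call in svcalls:
        if sv_types is not None and call.svtype not in sv_types:
            continue
        u = index.match(call.end1, L)
        v = index.match(call.end2, L)
        if u is None or v is None:
            continue
        if u == v:
            G.graph["self_junctions"][u].append(call)
            continue
        if G.has_edge(u, v):
            G.edges[u, v][EVIDENCE].append(call)
        else:
            G.add_edge(u, v, **{EVIDENCE: [call]})
    return G


def orient_to_auxiliary(G: nx.Graph) -> nx.DiGraph:
    """Orient G into the unit-weight auxiliary digraph H via deterministic DFS.

    Roots and neighbors are taken in ascending vertex id; each undirected
    edge is added to H directed the way the search first crosses it (tree
    edges parent-to-child, back edges descendant-to-ancestor) with weight 1.
    Every edge of G yields exactly one edge of H, so within each bridgeless
    piece of G the orientation is strongly connected and every undirected
    cycle survives as a directed cycle.
    """
    H = nx.DiGraph()
    H.graph["self_junctions"] = G.graph.get("self_junctions", {})
    for node, data in G.nodes(data=True):
        H.add_node(node, **data)

    seen_edges = set()
    visited = set()
    for root in sorted(G.nodes):
        if root in visited:
            continue
        visited.add(root)
        # iterative DFS; stack holds (vertex, sorted-neighbor iterator)
        stack = [(root, iter(sorted(G.neighbors(root))))]
        while stack:
            u, neighbors = stack[-1]
            advanced = False
            for v in neighbors:
                key = frozenset((u, v))
                if key in seen_edges:
                    continue
                seen_edges.add(key)
                H.add_edge(u, v, weight=1, **{PARENT_EDGE: tuple(sorted((u, v)))})
                if v not in visited:
                    visited.add(v)
                    stack.append((v, iter(sorted(G.neighbors(v)))))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
    return H


def edge_evidence(G: nx.Graph, u: int, v: int) -> List[SVCall]:
    """Evidence list of the undirected edge {u, v} of G."""
    return G.edges[u, v][EVIDENCE]
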