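"""Double-minute detection on the auxiliary digraph.

A circular double minute appears in the auxiliary digraph H as a directed
cycle, hence inside a strongly connected component.  Per SCC the detector
finds the minimum-weight directed cycle (unit edge weights, so the cycle
with the fewest amplicons), keeps it when it is long enough and its member
amplicons have uniform coverage, and reports it as a cyclic prediction.
Double minutes whose circle was not fully captured by the callers fall
through to a weakly-connected-component sweep and are reported as acyclic
candidates.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .graph_build import (
    EVIDENCE,
    PARENT_EDGE,
    build_amplicon_graph,
    compute_L,
    merge_cnv_calls,
    orient_to_auxiliary,
)
from .records import (
    Amplicon,
    DetectParams,
    DMPrediction,
    InsertSizeModel,
    RawCnvCall,
    SVCall,
    ValidationError,
)


def strongly_connected_components(H: nx.DiGraph) -> List[List[int]]:
    """SCCs of H as sorted vertex lists, ordered by smallest member id."""
    comps = [sorted(c) for c in nx.strongly_connected_components(H)]
    comps.sort(key=lambda c: c[0])
    return comps


def _bfs_shortest_path(H: nx.DiGraph, scc: frozenset, src: int, dst: int) -> Optional[List[int]]:
    """Shortest src->dst path confined to ``scc``; deterministic tie-break
    by visiting successors in ascending id order."""
    if src == dst:
        return [src]
    parent: Dict[int, int] = {src: src}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for v in sorted(H.successors(u)):
                if v in scc and v not in parent:
                    parent[v] = u
                    if v == dst:
                        path = [dst]
                        while path[-1] != src:
                            path.append(parent[path[-1]])
                        return path[::-1]
                    nxt.append(v)
        frontier = nxt
    return None


def _rotate_to_min(cycle: List[int]) -> List[int]:
    i = cycle.index(min(cycle))
    return cycle[i:] + cycle[:i]


def shortest_cycle_in_scc(H: nx.DiGraph, scc: Sequence[int]) -> Optional[List[int]]:
    """Minimum-weight directed cycle within one SCC, as an ordered vertex list.

    For every directed edge (u, v) inside the SCC the candidate cycle weight
    is 1 plus the shortest-path distance from v back to u (paths confined to
    the SCC).  The global minimum is returned, rotated to start at its
    smallest vertex id; among equal-weight candidates the lexicographically
    smallest rotated id sequence wins.  A singleton SCC yields a cycle only
    when its vertex carries a self-junction (a single-amplicon circle);
    otherwise None — the trivial one-vertex path is not a circle.
    """
    members = frozenset(scc)
    if len(members) == 1:
        v = next(iter(members))
        if H.graph.get("self_junctions", {}).get(v):
            return [v]
        return None
    best: Optional[Tuple[int, List[int]]] = None
    for u, v in sorted(H.edges):
        if u not in members or v not in members:
            continue
        back = _bfs_shortest_path(H, members, v, u)
        if back is None:
            continue
        cycle = _rotate_to_min([u] + back[:-1])
        key = (len(cycle), cycle)
        if best is None or key < best:
            best = key
    return None if best is None else best[1]


def coverage_uniform(amplicons: Sequence[Amplicon]) -> bool:
    """True when (max - min) coverage < mean coverage over the members.

    Double-minute amplicons share the circle's copy number, so their read
    depths should be alike; the spread is compared against the candidate's
    own mean.  Scale-invariant: multiplying all coverages by c > 0 does not
    change the outcome.
    """
    covs = [a.coverage for a in amplicons]
    if any(c is None for c in covs):
        raise ValidationError(
            "coverage filter requires a coverage for every amplicon; "
            "supply a coverage column or a depth table, or disable the filter"
        )
    return (max(covs) - min(covs)) < (sum(covs) / len(covs))


def _cycle_junctions(G_or_H, cycle: List[int]) -> List[Tuple[Tuple[int, int], List[SVCall]]]:
    """Evidence for each consecutive cycle edge (including last->first)."""
    out = []
    n = len(cycle)
    if n == 1:
        v = cycle[0]
        ev = G_or_H.graph.get("self_junctions", {}).get(v, [])
        return [((v, v), list(ev))]
    for i in range(n):
        u, v = cycle[i], cycle[(i + 1) % n]
        edge = tuple(sorted((u, v)))
        if G_or_H.has_edge(u, v):
            ev = G_or_H.edges[u, v].get(EVIDENCE, [])
        else:
            ev = G_or_H.edges[v, u].get(EVIDENCE, [])
        out.append((edge, list(ev)))
    return out


def _amplicon(H, vid: int) -> Amplicon:
    return H.nodes[vid]["amplicon"]


def find_cyclic_dms(H: nx.DiGraph, params: DetectParams = DetectParams()) -> List[DMPrediction]:
    """Cyclic double-minute predictions: one shortest cycle per SCC.

    A cycle is reported when its length reaches ``params.min_amplicons``
    (singletons additionally require ``allow_singleton``) and, if the
    coverage filter is on, its member coverages are uniform.  Predictions
    are ordered by their smallest member id; dm_ids are dense from 0.
    """
    preds: List[DMPrediction] = []
    for scc in strongly_connected_components(H):
        cycle = shortest_cycle_in_scc(H, scc)
        if cycle is None:
            continue
        if len(cycle) == 1 and not params.allow_singleton:
            continue
        if len(cycle) < params.min_amplicons:
            continue
        amps = [_amplicon(H, v) for v in cycle]
        if params.coverage_filter and not coverage_uniform(amps):
            continue
        junctions = _cycle_junctions(H, cycle)
        preds.append(DMPrediction(len(preds), amps, junctions, cyclic=True))
    return preds


def find_acyclic_dms(
    H: nx.DiGraph,
    cyclic_preds: Sequence[DMPrediction],
    params: DetectParams = DetectParams(),
) -> List[DMPrediction]:
    """Acyclic candidates: weakly connected components of H that contain no
    cyclic prediction, have at least ``min_amplicons`` vertices and (when
    filtering) uniform coverage.

    The component is reported whole, members in ascending id order with all
    component edges as junctions; no path extraction is attempted, so the
    shape may be a path, a tree or a star.  dm_ids continue after the cyclic
    predictions.
    """
    claimed = {v for pred in cyclic_preds for v in pred.amplicon_ids}
    preds: List[DMPrediction] = []
    comps = [sorted(c) for c in nx.weakly_connected_components(H)]
    comps.sort(key=lambda c: c[0])
    next_id = len(cyclic_preds)
    for comp in comps:
        if claimed.intersection(comp):
            continue
        if len(comp) < params.min_amplicons:
            continue
        amps = [_amplicon(H, v) for v in comp]
        apply_filter = params.coverage_filter and params.coverage_filter_acyclic
        if apply_filter and not coverage_uniform(amps):
            continue
        members = set(comp)
        junctions = [
            (tuple(sorted((u, v))), list(H.edges[u, v].get(EVIDENCE, [])))
            for u, v in sorted(H.edges)
            if u in members and v in members
        ]
        preds.append(DMPrediction(next_id, amps, junctions, cyclic=False))
        next_id += 1
    return preds


def detect_dms(
    amplicon_calls: Sequence[RawCnvCall],
    svcalls: Sequence[SVCall],
    model: InsertSizeModel = InsertSizeModel(400.0, 50.0, 3.0),
    params: DetectParams = DetectParams(),
    merge_gap: int = 1000,
    sv_types=None,
) -> List[DMPrediction]:
    """Full pipeline: merge CNV calls, build G, orient to H, detect.

    Returns cyclic predictions followed by acyclic ones.  Deterministic:
    identical inputs give identical outputs regardless of record order.
    """
    amplicons = merge_cnv_calls(amplicon_calls, merge_gap=merge_gap)
    if not amplicons:
        return []
    L = compute_L(model)
    G = build_amplicon_graph(amplicons, sorted(
        svcalls, key=lambda c: (c.end1.chrom, c.end1.pos, c.end2.chrom, c.end2.pos, c.svtype)
    ), L, sv_types=sv_types)
    H = orient_to_auxiliary(G)
    # copy undirected evidence onto H's directed edges for junction reporting
    for u, v, data in H.edges(data=True):
        pu, pv = data[PARENT_EDGE]
        data[EVIDENCE] = G.edges[pu, pv][EVIDENCE]
    cyclic = find_cyclic_dms(H, params)
    acyclic = find_acyclic_dms(H, cyclic, params)
    return cyclic + acyclic
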