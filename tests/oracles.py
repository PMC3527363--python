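"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own extraction code paths:
neighborhoods are recomputed from explicit predicate scans and from
networkx breadth-limited traversal, so implementation and oracle can
only agree by computing the same mathematical object.
"""

from __future__ import annotations

import networkx as nx

from interactograph.model import GeneRef, InteractionRecord


def record_multigraph(records: list[InteractionRecord]) -> nx.MultiGraph:
    """Undirected multigraph over ALL record endpoints (direction is
    ignored for neighborhood membership)."""
    g = nx.MultiGraph()
    for rec in records:
        g.add_node(rec.subject)
        g.add_node(rec.object)
        g.add_edge(rec.subject, rec.object, record_id=rec.record_id)
    return g


def oracle_r0(queryset: set[GeneRef], records) -> set[int]:
    return {
        r.record_id
        for r in records
        if r.subject in queryset and r.object in queryset
    }


def oracle_intermediates(queryset: set[GeneRef], records) -> set[GeneRef]:
    """Non-query genes with >=2 distinct query-member interactants."""
    g = record_multigraph(records)
    out = set()
    for node in g.nodes:
        if node in queryset:
            continue
        distinct_query_neighbors = {
            n for n in g.neighbors(node) if n in queryset and n != node
        }
        if len(distinct_query_neighbors) >= 2:
            out.add(node)
    return out


def oracle_r0_intermediates(queryset: set[GeneRef], records) -> set[int]:
    inter = oracle_intermediates(queryset, records)
    keep = set(oracle_r0(queryset, records))
    for r in records:
        a, b = r.subject, r.object
        if (a in queryset and b in inter) or (b in queryset and a in inter):
            keep.add(r.record_id)
    return keep


def oracle_r1(queryset: set[GeneRef], records) -> set[int]:
    return {
        r.record_id
        for r in records
        if r.subject in queryset or r.object in queryset
    }


def oracle_r2(queryset: set[GeneRef], records) -> set[int]:
    """Records with >=1 endpoint within graph distance 1 of the query
    set, computed with networkx ego graphs (a route independent of the
    shell-based implementation)."""
    g = record_multigraph(records)
    within1: set[GeneRef] = set(queryset)
    for q in queryset:
        if q in g:
            within1.update(nx.ego_graph(g, q, radius=1).nodes)
    return {
        r.record_id
        for r in records
        if r.subject in within1 or r.object in within1
    }


def graph_record_ids(graph) -> set[int]:
    """Flatten an InteractionGraph's merged edges back to record ids."""
    return {rid for e in graph.edges for rid in e.record_ids}


def oracle_nodes(queryset: set[GeneRef], records, kept_record_ids: set[int]) -> set[GeneRef]:
    """Expected node set: query members (isolated ones kept) plus every
    endpoint of a kept record."""
    nodes = set(queryset)
    by_id = {r.record_id: r for r in records}
    for rid in kept_record_ids:
        rec = by_id[rid]
        nodes.add(rec.subject)
        nodes.add(rec.object)
    return nodes
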