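"""Radius-scoped subgraph extraction — the algorithmic core.

Given an effective query set and the filtered interaction records, four
extraction modes produce the result graph:

* **R0** — only interactions between query members.
* **R0 with intermediates** — R0 plus, for every non-query gene with at
  least two *distinct* query-member interactants (direction ignored),
  that gene and its query-member edges.  Intermediate–intermediate
  edges are excluded.
* **R1** — every interaction touching at least one query member.
* **R2** — R1 plus every interaction touching an R1 interactant
  (including edges among the first shell).

Direction never affects neighborhood membership (a protein->DNA target
of a query gene is a neighbor) but is preserved on edges.  Duplicate
documentation of one relation (same pair, type, direction) is merged
into a single edge carrying every record id, so each edge remains
traceable to the knowledgebase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ConfigurationError
from .model import (
    GeneRef,
    InteractionRecord,
    InteractionType,
    Knowledgebase,
    NodeRole,
    QuerySpec,
    RadiusMode,
    sorted_refs,
)
from .resolve import expand_orthologs


@dataclass(frozen=True)
class Edge:
    """A merged, rendered edge: one documented relation, possibly backed
    by several records."""

    subject: GeneRef
    object: GeneRef
    interaction_type: InteractionType
    directed: bool
    record_ids: tuple[int, ...]

    @property
    def endpoints(self) -> tuple[GeneRef, GeneRef]:
        return (self.subject, self.object)


@dataclass
class InteractionGraph:
    """Result graph: gene nodes (hypernodes — one node per gene whatever
    molecular roles its edges imply), merged typed edges, query-group
    membership, and a role per node."""

    nodes: set[GeneRef] = field(default_factory=set)
    edges: list[Edge] = field(default_factory=list)
    query_membership: dict[int, frozenset[int]] = field(default_factory=dict)
    node_role: dict[int, NodeRole] = field(default_factory=dict)

    def degree(self, gene_id: int) -> int:
        return sum(
            1
            for e in self.edges
            if gene_id in (e.subject.gene_id, e.object.gene_id)
        )

    def sorted_nodes(self) -> list[GeneRef]:
        return sorted_refs(self.nodes)

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges, key=lambda e: e.record_ids)

    def to_jsonl(self) -> str:
        """Debug serialization: one JSON object per line; first a node
        manifest, then one line per merged edge."""
        lines = [
            json.dumps(
                {
                    "nodes": [
                        {
                            "gene_id": r.gene_id,
                            "tax_id": r.tax_id,
                            "role": self.node_role[r.gene_id].value,
                            "groups": sorted(self.query_membership.get(r.gene_id, ())),
                        }
                        for r in self.sorted_nodes()
                    ]
                },
                sort_keys=True,
            )
        ]
        for e in self.sorted_edges():
            lines.append(
                json.dumps(
                    {
                        "subject": e.subject.gene_id,
                        "object": e.object.gene_id,
                        "type": e.interaction_type.value,
                        "directed": e.directed,
                        "record_ids": list(e.record_ids),
                    },
                    sort_keys=True,
                )
            )
        return "\n".join(lines) + "\n"


def effective_query_set(spec: QuerySpec, kb: Knowledgebase) -> tuple[set[GeneRef], dict[int, frozenset[int]]]:
    """Resolve the query groups to the effective query gene set.

    All-ortholog mode (organism unset) expands every member across its
    homology group; group membership propagates to the orthologs it
    pulls in.  Single-organism mode keeps only members of that taxon and
    performs no expansion.  Returns (refs, gene_id -> group indices).
    """
    membership: dict[int, set[int]] = {}
    refs: set[GeneRef] = set()
    if spec.organism is not None:
        for idx, (_, members) in enumerate(spec.groups):
            for gid in members:
                ref = kb.gene_ref(gid)
                if ref is None or ref.tax_id != spec.organism:
                    continue
                refs.add(ref)
                membership.setdefault(gid, set()).add(idx)
    else:
        expansion = expand_orthologs(sorted(spec.all_members), kb)
        for idx, (_, members) in enumerate(spec.groups):
            for gid in members:
                for ref in expansion[gid]:
                    refs.add(ref)
                    membership.setdefault(ref.gene_id, set()).add(idx)
    return refs, {g: frozenset(s) for g, s in membership.items()}


def filter_records(kb: Knowledgebase, spec: QuerySpec) -> list[InteractionRecord]:
    """Apply the type/status/organism filters to the interaction table.

    Single-organism mode keeps only records whose BOTH endpoints belong
    to the organism, so single-species results contain no foreign genes.
    """
    if not spec.include_types:
        raise ConfigurationError("include_types is empty; every query would be empty")
    if not spec.include_status:
        raise ConfigurationError("include_status is empty; every query would be empty")
    out = []
    for rec in kb.interactions:
        if rec.interaction_type not in spec.include_types:
            continue
        if rec.annotation_status not in spec.include_status:
            continue
        if spec.organism is not None and not (
            rec.subject.tax_id == spec.organism and rec.object.tax_id == spec.organism
        ):
            continue
        out.append(rec)
    return out


def _base_graph(queryset: Iterable[GeneRef]) -> InteractionGraph:
    g = InteractionGraph()
    for ref in queryset:
        g.nodes.add(ref)
        g.node_role[ref.gene_id] = NodeRole.query
    return g


def _add_record(g: InteractionGraph, rec: InteractionRecord, role_for_new: NodeRole) -> None:
    for ref in rec.endpoints:
        if ref not in g.nodes:
            g.nodes.add(ref)
            g.node_role[ref.gene_id] = role_for_new
    g._raw_records.append(rec)  # type: ignore[attr-defined]


def extract_r0(queryset: set[GeneRef], records: list[InteractionRecord]) -> InteractionGraph:
    """Edges with both endpoints in the query set.  Query genes with no
    surviving interaction stay as isolated nodes so the user can see a
    queried gene returned nothing."""
    g = _base_graph(queryset)
    g._raw_records = []  # type: ignore[attr-defined]
    for rec in records:
        if rec.subject in queryset and rec.object in queryset:
            _add_record(g, rec, NodeRole.query)
    g.edges = merge_edges(g._raw_records)  # type: ignore[attr-defined]
    return g


def extract_r0_intermediates(
    queryset: set[GeneRef], records: list[InteractionRecord]
) -> InteractionGraph:
    """R0 edges, plus every non-query gene X with >=2 *distinct* query
    interactants together with its X–query edges.  Counting is by
    distinct gene (two records to one query gene do not qualify X);
    ortholog-expanded query members each count.  Intermediate–
    intermediate edges are not included."""
    g = extract_r0(queryset, records)
    query_neighbors: dict[GeneRef, set[GeneRef]] = {}
    for rec in records:
        s_in, o_in = rec.subject in queryset, rec.object in queryset
        if s_in and not o_in:
            query_neighbors.setdefault(rec.object, set()).add(rec.subject)
        elif o_in and not s_in:
            query_neighbors.setdefault(rec.subject, set()).add(rec.object)
    intermediates = {x for x, qs in query_neighbors.items() if len(qs) >= 2}
    for rec in records:
        s_in, o_in = rec.subject in queryset, rec.object in queryset
        if (s_in and rec.object in intermediates) or (o_in and rec.subject in intermediates):
            _add_record(g, rec, NodeRole.intermediate)
    g.edges = merge_edges(g._raw_records)  # type: ignore[attr-defined]
    return g


def extract_r1(queryset: set[GeneRef], records: list[InteractionRecord]) -> InteractionGraph:
    """Every record touching at least one query member; non-query
    endpoints become neighbors."""
    g = _base_graph(queryset)
    g._raw_records = []  # type: ignore[attr-defined]
    for rec in records:
        if rec.subject in queryset or rec.object in queryset:
            _add_record(g, rec, NodeRole.neighbor)
    g.edges = merge_edges(g._raw_records)  # type: ignore[attr-defined]
    return g


def extract_r2(queryset: set[GeneRef], records: list[InteractionRecord]) -> InteractionGraph:
    """R1 plus every record touching a first-shell interactant; brand-new
    endpoints are second shell.  First-shell/first-shell edges are
    included."""
    g = extract_r1(queryset, records)
    n1 = {ref for ref in g.nodes if g.node_role[ref.gene_id] is NodeRole.neighbor}
    included = {id(r) for r in g._raw_records}  # type: ignore[attr-defined]
    for rec in records:
        if id(rec) in included:
            continue
        if rec.subject in n1 or rec.object in n1:
            _add_record(g, rec, NodeRole.second_shell)
    g.edges = merge_edges(g._raw_records)  # type: ignore[attr-defined]
    return g


_EXTRACTORS = {
    RadiusMode.R0: extract_r0,
    RadiusMode.R0_INTERMEDIATES: extract_r0_intermediates,
    RadiusMode.R1: extract_r1,
    RadiusMode.R2: extract_r2,
}


def merge_edges(records: list[InteractionRecord]) -> list[Edge]:
    """Merge duplicate documentation — same unordered pair (ordered for
    directed types), same type, same direction — into single edges with
    concatenated record ids, deterministically ordered."""
    merged: dict[tuple, list[InteractionRecord]] = {}
    for rec in records:
        merged.setdefault(rec.pair_key(), []).append(rec)
    edges = []
    for key, recs in merged.items():
        recs = sorted(recs, key=lambda r: r.record_id)
        first = recs[0]
        if first.directed:
            subject, obj = first.subject, first.object
        else:
            subject, obj = sorted((first.subject, first.object))
        edges.append(
            Edge(
                subject=subject,
                object=obj,
                interaction_type=first.interaction_type,
                directed=first.directed,
                record_ids=tuple(r.record_id for r in recs),
            )
        )
    edges.sort(key=lambda e: e.record_ids)
    return edges


def extract(spec: QuerySpec, kb: Knowledgebase) -> InteractionGraph:
    """Full pipeline: effective query set -> record filters -> mode
    extractor -> duplicate-edge merge."""
    queryset, membership = effective_query_set(spec, kb)
    records = filter_records(kb, spec)
    g = _EXTRACTORS[spec.radius_mode](queryset, records)
    g.query_membership = membership
    g.edges = merge_edges(g._raw_records)  # type: ignore[attr-defined]
    del g._raw_records  # type: ignore[attr-defined]
    return g
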