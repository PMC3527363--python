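"""Compound (stacked) ortholog nodes.

In all-ortholog mode, orthologous genes are drawn as one stacked node so
knowledge documented in one organism sits beside its counterpart in
another.  A gene joins a stack only when (a) it shares a homology group
with another drawn gene and (b) it has at least one edge that actually
appears in the result graph — isolated query nodes never stack.  In
single-organism mode every node is a singleton.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .extract import InteractionGraph
from .model import GeneRef, Knowledgebase, QuerySpec, sorted_refs


@dataclass(frozen=True)
class Stack:
    homologene_id: int
    members: tuple[GeneRef, ...]  # ordered by (tax_id, gene_id)


@dataclass
class CompoundPartition:
    """Partition of the graph's nodes into ortholog stacks (>=2 members,
    each with a rendered edge) and singletons."""

    stacks: list[Stack] = field(default_factory=list)
    singletons: list[GeneRef] = field(default_factory=list)

    def all_nodes(self) -> list[GeneRef]:
        out = [m for s in self.stacks for m in s.members]
        out.extend(self.singletons)
        return out

    def stack_of(self, gene_id: int) -> Stack | None:
        for s in self.stacks:
            if any(m.gene_id == gene_id for m in s.members):
                return s
        return None


def build_partition(
    graph: InteractionGraph,
    kb: Knowledgebase,
    spec: QuerySpec,
) -> CompoundPartition:
    """Group graph nodes into compound nodes by homology group.

    Two nodes stack iff they share a homologene id AND each has >=1 edge
    in the graph.  Members are ordered by tax id.  Single-organism mode
    yields all singletons.
    """
    part = CompoundPartition()
    nodes = sorted_refs(graph.nodes)
    if spec.organism is not None:
        part.singletons = nodes
        return part

    with_edges = {
        gid
        for e in graph.edges
        for gid in (e.subject.gene_id, e.object.gene_id)
    }
    by_group: dict[int, list[GeneRef]] = {}
    for ref in nodes:
        hid = kb.homologene_id_of(ref.gene_id)
        if hid is not None and ref.gene_id in with_edges:
            by_group.setdefault(hid, []).append(ref)

    stacked: set[GeneRef] = set()
    for hid in sorted(by_group):
        members = by_group[hid]
        if len(members) >= 2:
            part.stacks.append(Stack(homologene_id=hid, members=tuple(members)))
            stacked.update(members)
    part.singletons = [r for r in nodes if r not in stacked]
    return part
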