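"""Core domain types.

The knowledgebase mirrors the three NCBI-style tables a curation database
is built from: an interaction table (one documented interaction per row,
each backed by PubMed citations), a gene-info table (Entrez-style identity
cards) and a homology table (HomoloGene-style ortholog groups).  All types
are plain frozen dataclasses; validation is explicit so that file loaders
can attribute violations to line numbers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional


class InteractionType(enum.Enum):
    """Kind of documented interaction; the TSV code is the enum value."""

    protein_protein = "PP"
    protein_dna = "PD"
    genetic = "GI"
    other = "OTHER"

    @classmethod
    def from_code(cls, code: str) -> "InteractionType":
        try:
            return cls(code)
        except ValueError:
            raise ValueError(f"unknown interaction type code {code!r}") from None


class AnnotationStatus(enum.Enum):
    curated = "curated"
    user_submitted = "user"


class RadiusMode(enum.Enum):
    """Query-scoped network radius.

    R0 keeps only interactions among query genes; R0_INTERMEDIATES adds
    non-query genes interacting with >=2 distinct query members; R1 keeps
    every interaction touching a query gene; R2 additionally keeps every
    interaction touching an R1 interactant.
    """

    R0 = "0"
    R0_INTERMEDIATES = "0i"
    R1 = "1"
    R2 = "2"


class NodeRole(enum.Enum):
    query = "query"
    intermediate = "intermediate"
    neighbor = "neighbor"
    second_shell = "second_shell"


@dataclass(frozen=True, order=True)
class GeneRef:
    """An Entrez-style gene identifier pinned to an NCBI-style taxon."""

    tax_id: int
    gene_id: int

    def __post_init__(self) -> None:
        if self.gene_id <= 0 or self.tax_id <= 0:
            raise ValueError("gene_id and tax_id must be positive integers")


@dataclass(frozen=True)
class InteractionRecord:
    """One documented interaction between two genes/gene products.

    ``directed`` is true exactly for protein->DNA records (regulator to
    target); protein-protein and genetic interactions are undirected.
    Every record carries at least one PubMed id, and user-submitted
    records carry the submitter's name.
    """

    record_id: int
    subject: GeneRef
    object: GeneRef
    interaction_type: InteractionType
    directed: bool
    pubmed_ids: tuple[int, ...]
    submitter: Optional[str] = None
    annotation_status: AnnotationStatus = AnnotationStatus.curated

    def validate(self) -> None:
        if self.record_id <= 0:
            raise ValueError("record_id must be a positive integer")
        if not self.pubmed_ids:
            raise ValueError("pubmed_ids must be non-empty")
        if any(p <= 0 for p in self.pubmed_ids):
            raise ValueError("pubmed_ids must be positive integers")
        expect_directed = self.interaction_type is InteractionType.protein_dna
        if self.directed != expect_directed:
            raise ValueError(
                f"direction flag inconsistent with type "
                f"{self.interaction_type.value} (directed={self.directed})"
            )
        if self.annotation_status is AnnotationStatus.user_submitted and not self.submitter:
            raise ValueError("user-submitted records must name a submitter")

    @property
    def endpoints(self) -> tuple[GeneRef, GeneRef]:
        return (self.subject, self.object)

    def pair_key(self) -> tuple:
        """Identity of the documented relation: unordered gene pair for
        undirected types, ordered for protein->DNA."""
        if self.directed:
            return (self.subject, self.object, self.interaction_type)
        a, b = sorted((self.subject, self.object))
        return (a, b, self.interaction_type)


@dataclass(frozen=True)
class GeneInfo:
    """Identity card for one gene: official symbol, synonyms, free-text
    description and flat GO term strings (terms are opaque; no ontology
    traversal)."""

    gene: GeneRef
    official_symbol: str
    synonyms: tuple[str, ...] = ()
    description: str = ""
    go_terms: tuple[str, ...] = ()

    @property
    def gene_id(self) -> int:
        return self.gene.gene_id

    @property
    def tax_id(self) -> int:
        return self.gene.tax_id


@dataclass(frozen=True)
class HomologyGroup:
    """An ortholog group: genes sharing one HomoloGene-style group id."""

    homologene_id: int
    members: tuple[GeneRef, ...]

    def __post_init__(self) -> None:
        if self.homologene_id <= 0:
            raise ValueError("homologene_id must be positive")
        if len(self.members) < 2:
            raise ValueError("a homology group needs >=2 members")


class ChangeAction(enum.Enum):
    add = "add"
    revert = "revert"


@dataclass(frozen=True)
class ChangeEvent:
    """One entry of the append-only history: a user-submitted record was
    added, or a previously added record was reverted away.  ``record`` may
    be None only for revert events re-loaded from disk whose record is no
    longer present in the interaction table."""

    sequence_no: int
    action: ChangeAction
    record: Optional[InteractionRecord]
    user: str
    timestamp: str
    record_id_hint: Optional[int] = None

    @property
    def record_id(self) -> int:
        if self.record is not None:
            return self.record.record_id
        if self.record_id_hint is None:
            raise ValueError("change event carries neither record nor record id")
        return self.record_id_hint


@dataclass
class Knowledgebase:
    """In-memory knowledgebase: interaction list, gene index, homology
    groups and the append-only change history."""

    interactions: list[InteractionRecord] = field(default_factory=list)
    genes: dict[int, GeneInfo] = field(default_factory=dict)
    homology_groups: dict[int, HomologyGroup] = field(default_factory=dict)
    history: list[ChangeEvent] = field(default_factory=list)

    # derived index: gene_id -> homologene_id
    _gene_to_group: dict[int, int] = field(default_factory=dict, repr=False)

    def reindex(self) -> None:
        self._gene_to_group = {
            m.gene_id: g.homologene_id
            for g in self.homology_groups.values()
            for m in g.members
        }

    def homologene_id_of(self, gene_id: int) -> Optional[int]:
        if not self._gene_to_group and self.homology_groups:
            self.reindex()
        return self._gene_to_group.get(gene_id)

    def group_of(self, gene_id: int) -> Optional[HomologyGroup]:
        hid = self.homologene_id_of(gene_id)
        return self.homology_groups.get(hid) if hid is not None else None

    def record_by_id(self, record_id: int) -> InteractionRecord:
        for rec in self.interactions:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)

    def gene_ref(self, gene_id: int) -> Optional[GeneRef]:
        info = self.genes.get(gene_id)
        return info.gene if info is not None else None

    def interacting_gene_ids(self) -> set[int]:
        out: set[int] = set()
        for rec in self.interactions:
            out.add(rec.subject.gene_id)
            out.add(rec.object.gene_id)
        return out

    def next_record_id(self) -> int:
        return 1 + max((r.record_id for r in self.interactions), default=0)

    def next_sequence_no(self) -> int:
        return 1 + max((e.sequence_no for e in self.history), default=0)

    def label_of(self, ref: GeneRef) -> str:
        """Official symbol when annotated, raw gene_id otherwise (orphan
        GeneRefs are tolerated)."""
        info = self.genes.get(ref.gene_id)
        return info.official_symbol if info is not None else str(ref.gene_id)


@dataclass(frozen=True)
class QuerySpec:
    """A validated query: up to three named groups of resolved gene ids,
    a radius mode, an optional single-organism constraint (absent means
    all-ortholog mode) and type/status filters."""

    groups: tuple[tuple[str, tuple[int, ...]], ...]
    radius_mode: RadiusMode = RadiusMode.R1
    organism: Optional[int] = None
    include_types: frozenset[InteractionType] = frozenset(InteractionType)
    include_status: frozenset[AnnotationStatus] = frozenset(AnnotationStatus)

    def __post_init__(self) -> None:
        if not 1 <= len(self.groups) <= 3:
            raise ValueError("a query carries between 1 and 3 groups")
        for name, members in self.groups:
            if not members:
                raise ValueError(f"group {name!r} is empty")

    @property
    def all_members(self) -> set[int]:
        return {g for _, members in self.groups for g in members}

    def groups_of(self, gene_id: int) -> frozenset[int]:
        return frozenset(
            i for i, (_, members) in enumerate(self.groups) if gene_id in members
        )


DEFAULT_GROUP_NAMES = ("Query Group 1", "Query Group 2", "Query Group 3")


def default_group_name(index: int) -> str:
    return DEFAULT_GROUP_NAMES[index]


def sorted_refs(refs: Iterable[GeneRef]) -> list[GeneRef]:
    """Canonical node order: (tax_id, gene_id)."""
    return sorted(refs, key=lambda r: (r.tax_id, r.gene_id))
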