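"""Shared builders for handmade knowledgebases."""

from __future__ import annotations

from interactograph.model import (
    AnnotationStatus,
    GeneInfo,
    GeneRef,
    HomologyGroup,
    InteractionRecord,
    InteractionType,
    Knowledgebase,
)

HUMAN, MOUSE, RAT = 9606, 10090, 10116


def ref(gene_id: int, tax_id: int = HUMAN) -> GeneRef:
    return GeneRef(tax_id=tax_id, gene_id=gene_id)


def gene(
    gene_id: int,
    symbol: str,
    tax_id: int = HUMAN,
    synonyms: tuple[str, ...] = (),
    description: str = "",
    go_terms: tuple[str, ...] = (),
) -> GeneInfo:
    return GeneInfo(
        gene=ref(gene_id, tax_id),
        official_symbol=symbol,
        synonyms=synonyms,
        description=description,
        go_terms=go_terms,
    )


def record(
    record_id: int,
    subject: GeneRef,
    object: GeneRef,
    itype: InteractionType = InteractionType.protein_protein,
    pubmed: tuple[int, ...] = (11111111,),
    submitter: str | None = None,
) -> InteractionRecord:
    rec = InteractionRecord(
        record_id=record_id,
        subject=subject,
        object=object,
        interaction_type=itype,
        directed=itype is InteractionType.protein_dna,
        pubmed_ids=pubmed,
        submitter=submitter,
        annotation_status=(
            AnnotationStatus.user_submitted if submitter else AnnotationStatus.curated
        ),
    )
    rec.validate()
    return rec


def build_kb(
    genes: list[GeneInfo] = (),
    interactions: list[InteractionRecord] = (),
    groups: dict[int, list[GeneRef]] | None = None,
) -> Knowledgebase:
    kb = Knowledgebase()
    for g in genes:
        kb.genes[g.gene_id] = g
    kb.interactions = list(interactions)
    for hid, members in (groups or {}).items():
        kb.homology_groups[hid] = HomologyGroup(
            homologene_id=hid, members=tuple(sorted(members))
        )
    kb.reindex()
    return kb
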