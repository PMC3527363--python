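"""Gene lookup: keyword search over descriptions, GO terms, symbols and
synonyms, with a per-hit flag marking genes that have documented
interactions in the knowledgebase.  Matching is case-insensitive
contiguous-substring (a multi-word keyword matches as a phrase); GO
terms are opaque strings, no ontology traversal."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import GeneRef, Knowledgebase

MATCH_FIELDS = ("description", "go_term", "symbol", "synonym")


@dataclass(frozen=True)
class LookupHit:
    gene: GeneRef
    matched_fields: frozenset[str]
    supported_by_kb: bool
    # reserved for future integration with expression-correlation tools
    supported_by_starnet: Optional[bool] = None


def keyword_search(
    keyword: str,
    kb: Knowledgebase,
    organism: Optional[int] = None,
) -> list[LookupHit]:
    """Search all four annotation fields simultaneously.

    Hits are sorted by number of matched fields (descending) then
    gene id; an empty result list is a valid outcome.
    """
    needle = keyword.strip().casefold()
    if not needle:
        raise ValueError("empty keyword")
    supported = kb.interacting_gene_ids()
    hits: list[LookupHit] = []
    for gid in sorted(kb.genes):
        info = kb.genes[gid]
        if organism is not None and info.tax_id != organism:
            continue
        matched = set()
        if needle in info.description.casefold():
            matched.add("description")
        if any(needle in t.casefold() for t in info.go_terms):
            matched.add("go_term")
        if needle in info.official_symbol.casefold():
            matched.add("symbol")
        if any(needle in s.casefold() for s in info.synonyms):
            matched.add("synonym")
        if matched:
            hits.append(
                LookupHit(
                    gene=info.gene,
                    matched_fields=frozenset(matched),
                    supported_by_kb=gid in supported,
                )
            )
    hits.sort(key=lambda h: (-len(h.matched_fields), h.gene.gene_id))
    return hits


def go_term_gene_list(
    term_substring: str,
    kb: Knowledgebase,
    organism: Optional[int] = None,
) -> list[int]:
    """Gene ids annotated with >=1 GO term containing the substring;
    suitable as direct input for building a query group."""
    return sorted(
        h.gene.gene_id
        for h in keyword_search(term_substring, kb, organism)
        if "go_term" in h.matched_fields
    )
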