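"""Query-string parsing and gene identifier resolution.

Canonical query grammar::

    query := group ("/" group){0,2}
    group := token ("," token)*

A token is resolved with precedence numeric-ID > official symbol >
synonym, case-insensitively for symbols and synonyms.  When an organism
is given, symbol/synonym search is confined to it; otherwise a symbol
resolving to exactly one gene across all taxa is accepted and a
multi-taxon match is reported as ambiguous (never a silent pick).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import QueryFormatError, ResolutionError
from .model import (
    AnnotationStatus,
    GeneRef,
    InteractionType,
    Knowledgebase,
    QuerySpec,
    RadiusMode,
    default_group_name,
)

MAX_GROUPS = 3


class ResolutionOutcome(enum.Enum):
    resolved_id = "resolved_id"
    resolved_symbol = "resolved_symbol"
    resolved_synonym = "resolved_synonym"
    ambiguous = "ambiguous"
    unknown = "unknown"


@dataclass(frozen=True)
class ResolutionReport:
    token: str
    outcome: ResolutionOutcome
    candidates: tuple[GeneRef, ...] = ()
    note: str = ""

    @property
    def resolved(self) -> bool:
        return self.outcome in (
            ResolutionOutcome.resolved_id,
            ResolutionOutcome.resolved_symbol,
            ResolutionOutcome.resolved_synonym,
        )

    @property
    def gene_id(self) -> int:
        if not self.resolved:
            raise ValueError(f"token {self.token!r} did not resolve")
        return self.candidates[0].gene_id


def resolve_token(
    token: str,
    kb: Knowledgebase,
    organism: Optional[int] = None,
) -> ResolutionReport:
    """Resolve one query token to a gene.

    Numeric tokens are gene ids (a gene whose symbol is all digits is
    reachable only by id).  Symbol matches shadow synonym matches for
    the same token; a synonym hitting >=2 genes in scope is ambiguous.
    """
    token = token.strip()
    if not token:
        raise ValueError("empty token")

    if token.isdigit():
        gid = int(token)
        ref = kb.gene_ref(gid)
        if ref is None:
            return ResolutionReport(token, ResolutionOutcome.unknown)
        return ResolutionReport(token, ResolutionOutcome.resolved_id, (ref,))

    folded = token.casefold()
    in_scope = [
        info for info in kb.genes.values()
        if organism is None or info.tax_id == organism
    ]

    symbol_hits = [i.gene for i in in_scope if i.official_symbol.casefold() == folded]
    if len(symbol_hits) == 1:
        return ResolutionReport(token, ResolutionOutcome.resolved_symbol, tuple(symbol_hits))
    if len(symbol_hits) >= 2:
        return ResolutionReport(
            token, ResolutionOutcome.ambiguous, tuple(sorted(symbol_hits)),
            note="official symbol matches multiple taxa; specify an organism",
        )

    synonym_hits = [
        i.gene for i in in_scope
        if any(s.casefold() == folded for s in i.synonyms)
    ]
    if len(synonym_hits) == 1:
        return ResolutionReport(token, ResolutionOutcome.resolved_synonym, tuple(synonym_hits))
    if len(synonym_hits) >= 2:
        return ResolutionReport(
            token, ResolutionOutcome.ambiguous, tuple(sorted(synonym_hits)),
            note="synonym matches multiple genes",
        )
    return ResolutionReport(token, ResolutionOutcome.unknown)


def split_query_string(query_string: str) -> list[list[str]]:
    """Split a raw query string into trimmed token groups, enforcing the
    <=3-group grammar.  Trailing empty tokens after a final comma are
    forgiven; an empty group between slashes is an error."""
    if not query_string or not query_string.strip():
        raise QueryFormatError("empty query string")
    segments = query_string.split("/")
    if len(segments) > MAX_GROUPS:
        raise QueryFormatError(
            f"at most {MAX_GROUPS} query groups are allowed, got {len(segments)}"
        )
    groups: list[list[str]] = []
    for i, segment in enumerate(segments):
        tokens = [t.strip() for t in segment.split(",")]
        while tokens and tokens[-1] == "":
            tokens.pop()
        if not tokens:
            raise QueryFormatError(f"query group {i + 1} is empty")
        if any(t == "" for t in tokens):
            raise QueryFormatError(f"query group {i + 1} contains an empty token")
        groups.append(tokens)
    return groups


def parse_query(
    query_string: str,
    kb: Knowledgebase,
    group_names: Optional[Sequence[str]] = None,
    organism: Optional[int] = None,
    radius_mode: RadiusMode = RadiusMode.R1,
    include_types: frozenset[InteractionType] = frozenset(InteractionType),
    include_status: frozenset[AnnotationStatus] = frozenset(AnnotationStatus),
) -> tuple[QuerySpec, list[ResolutionReport]]:
    """Parse and resolve a query string into a validated QuerySpec.

    Every token must resolve; otherwise a :class:`ResolutionError`
    carrying all reports (including the successful ones) is raised —
    tokens are never silently dropped.
    """
    token_groups = split_query_string(query_string)
    if group_names is not None and len(group_names) < len(token_groups):
        raise QueryFormatError(
            f"{len(token_groups)} groups but only {len(group_names)} group names"
        )
    reports: list[ResolutionReport] = []
    resolved_groups: list[tuple[str, tuple[int, ...]]] = []
    ok = True
    for i, tokens in enumerate(token_groups):
        name = group_names[i] if group_names is not None else default_group_name(i)
        members: list[int] = []
        for token in tokens:
            report = resolve_token(token, kb, organism)
            reports.append(report)
            if report.resolved:
                members.append(report.gene_id)
            else:
                ok = False
        resolved_groups.append((name, tuple(members)))
    if not ok:
        raise ResolutionError(reports)
    spec = QuerySpec(
        groups=tuple(resolved_groups),
        radius_mode=radius_mode,
        organism=organism,
        include_types=include_types,
        include_status=include_status,
    )
    return spec, reports


def format_query(spec: QuerySpec) -> str:
    """Canonical query string for a spec: gene ids, comma-joined within
    groups, '/'-joined between.  ``parse_query(format_query(s))`` gives
    back the same groups."""
    return "/".join(
        ",".join(str(g) for g in members) for _, members in spec.groups
    )


def expand_orthologs(
    gene_ids: Sequence[int],
    kb: Knowledgebase,
) -> dict[int, set[GeneRef]]:
    """Map each gene to itself plus every gene sharing its homology
    group.  Genes without a group (or absent from gene_info) map to the
    singleton containing themselves.  Total and idempotent."""
    out: dict[int, set[GeneRef]] = {}
    for gid in gene_ids:
        self_ref = kb.gene_ref(gid)
        group = kb.group_of(gid)
        expansion: set[GeneRef] = set()
        if self_ref is not None:
            expansion.add(self_ref)
        if group is not None:
            expansion.update(group.members)
        if not expansion:
            # orphan id: keep it with an unknown-taxon placeholder taxon 1
            expansion.add(GeneRef(tax_id=1, gene_id=gid))
        out[gid] = expansion
    return out
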