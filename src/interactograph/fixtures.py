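"""Seeded synthetic knowledgebase generator.

Documented interaction networks are scale-free: most genes have few
documented partners while a handful of intensively studied hubs have
very many.  The generator emulates that shape with preferential
attachment: each new interaction reuses an endpoint drawn from the
multiset of previous endpoints with probability ``PREF_P`` and draws a
uniform gene otherwise, so early/lucky genes accumulate degree.

Everything is a pure function of the arguments including the seed, so
fixtures are reproducible byte-for-byte.
"""

from __future__ import annotations

import random
from typing import Mapping, Optional

from .errors import ConfigurationError
from .model import (
    AnnotationStatus,
    GeneInfo,
    GeneRef,
    HomologyGroup,
    InteractionRecord,
    InteractionType,
    Knowledgebase,
)

# NCBI-style taxon ids: human, mouse, rat, fly, zebrafish, worm, yeast, E. coli
TAXON_POOL = (9606, 10090, 10116, 7227, 7955, 6239, 4932, 511145)

DEFAULT_TYPE_MIX: dict[InteractionType, float] = {
    InteractionType.protein_protein: 0.60,
    InteractionType.protein_dna: 0.20,
    InteractionType.genetic: 0.15,
    InteractionType.other: 0.05,
}

# probability that an interaction endpoint is drawn preferentially
# (proportional to current degree) rather than uniformly; high enough
# that hubs clearly separate from the low-degree bulk
PREF_P = 0.9

USER_SUBMITTED_FRACTION = 0.1

_DESCRIPTION_PHRASES = (
    "transcription factor",
    "cardiac muscle development regulator",
    "alcohol dehydrogenase family member",
    "bone remodeling factor",
    "kinase in growth signaling",
    "chromatin remodeling subunit",
    "cell cycle checkpoint component",
    "membrane receptor",
)

_GO_VOCAB = (
    "transcription regulation",
    "cardiac muscle development",
    "alcohol metabolic process",
    "bone remodeling",
    "protein phosphorylation",
    "chromatin organization",
    "cell cycle",
    "signal transduction",
    "apoptotic process",
    "DNA repair",
)

_FIRST_GENE_ID = 1001


def generate_fixture(
    n_genes: int,
    n_taxa: int = 1,
    n_interactions: int = 0,
    ortholog_fraction: float = 0.0,
    type_mix: Optional[Mapping[InteractionType, float]] = None,
    seed: int = 0,
    taxon_weights: Optional[tuple[float, ...]] = None,
) -> Knowledgebase:
    """Generate a synthetic knowledgebase.

    Parameters
    ----------
    n_genes:
        Number of genes (>=2), split round-robin across ``n_taxa`` taxa
        drawn from a fixed NCBI-style taxon pool.
    n_interactions:
        Number of interaction records, attached with a preferential-
        attachment endpoint rule so the degree distribution is hub-heavy.
    ortholog_fraction:
        Fraction of genes placed into cross-taxon homology groups
        (group size 2..min(3, n_taxa), one member per taxon when possible).
    type_mix:
        Weight per interaction type; defaults to a protein-protein
        dominated mix.
    seed:
        Seed for the single PRNG driving every random choice.
    taxon_weights:
        Optional relative gene counts per taxon (length ``n_taxa``).
        Real curation corpora are heavily skewed toward a few
        intensively studied organisms; the default is an even
        round-robin split.
    """
    if n_genes < 2:
        raise ConfigurationError("n_genes must be >= 2")
    if n_interactions < 0:
        raise ConfigurationError("n_interactions must be >= 0")
    if not 1 <= n_taxa <= len(TAXON_POOL):
        raise ConfigurationError(f"n_taxa must be in 1..{len(TAXON_POOL)}")
    if not 0.0 <= ortholog_fraction <= 1.0:
        raise ConfigurationError("ortholog_fraction must be in [0, 1]")
    mix = dict(type_mix) if type_mix is not None else dict(DEFAULT_TYPE_MIX)
    if not mix or sum(mix.values()) <= 0:
        raise ConfigurationError("type_mix weights must sum to a positive value")

    rng = random.Random(seed)
    taxa = TAXON_POOL[:n_taxa]
    kb = Knowledgebase()

    taxon_of = _taxon_assignment(n_genes, taxa, taxon_weights)
    refs: list[GeneRef] = []
    for i in range(n_genes):
        gid = _FIRST_GENE_ID + i
        ref = GeneRef(tax_id=taxon_of[i], gene_id=gid)
        refs.append(ref)
        synonyms = tuple(
            f"SYN{rng.randrange(max(2, n_genes // 2))}"
            for _ in range(rng.choice((0, 0, 1, 1, 2)))
        )
        kb.genes[gid] = GeneInfo(
            gene=ref,
            official_symbol=f"G{gid}",
            synonyms=synonyms,
            description=f"{rng.choice(_DESCRIPTION_PHRASES)} {gid}",
            go_terms=tuple(
                sorted(rng.sample(_GO_VOCAB, rng.randint(1, 3)))
            ),
        )

    _assign_homology(kb, refs, ortholog_fraction, n_taxa, rng)
    _attach_interactions(kb, refs, n_interactions, mix, rng)
    kb.reindex()
    return kb


def _taxon_assignment(n_genes, taxa, taxon_weights) -> list[int]:
    """Per-gene taxon: round-robin by default, largest-remainder
    apportionment when weights are given (deterministic)."""
    if taxon_weights is None:
        return [taxa[i % len(taxa)] for i in range(n_genes)]
    if len(taxon_weights) != len(taxa) or any(w < 0 for w in taxon_weights):
        raise ConfigurationError("taxon_weights must be n_taxa non-negative values")
    total = sum(taxon_weights)
    if total <= 0:
        raise ConfigurationError("taxon_weights must sum to a positive value")
    quotas = [n_genes * w / total for w in taxon_weights]
    counts = [int(q) for q in quotas]
    remainders = sorted(
        range(len(taxa)), key=lambda i: (quotas[i] - counts[i], -i), reverse=True
    )
    for i in range(n_genes - sum(counts)):
        counts[remainders[i % len(taxa)]] += 1
    out: list[int] = []
    for t, c in zip(taxa, counts):
        out.extend([t] * c)
    return out


def _assign_homology(kb, refs, ortholog_fraction, n_taxa, rng) -> None:
    n_orth = int(round(ortholog_fraction * len(refs)))
    if n_orth < 2:
        return
    by_taxon: dict[int, list[GeneRef]] = {}
    pool = refs[:]
    rng.shuffle(pool)
    pool = pool[:n_orth]
    for ref in pool:
        by_taxon.setdefault(ref.tax_id, []).append(ref)
    hid = 1
    # Cross-taxon groups preferred: repeatedly take one gene from each of
    # the 2-3 currently largest taxon buckets.  With one taxon the groups
    # are within-taxon paralog groups (permitted).
    while True:
        buckets = sorted(
            (b for b in by_taxon.values() if b), key=len, reverse=True
        )
        if not buckets:
            break
        size = min(len(buckets), max(2, min(3, n_taxa)))
        if size >= 2:
            members = tuple(sorted(b.pop() for b in buckets[:size]))
        elif len(buckets[0]) >= 2:
            members = tuple(sorted(buckets[0].pop() for _ in range(min(3, len(buckets[0])))))
        else:
            break
        kb.homology_groups[hid] = HomologyGroup(homologene_id=hid, members=members)
        hid += 1


def _attach_interactions(kb, refs, n_interactions, mix, rng) -> None:
    types = sorted(mix, key=lambda t: t.value)
    weights = [mix[t] for t in types]
    # endpoint pool seeded with every gene once so all genes are reachable
    endpoint_pool: list[GeneRef] = refs[:]

    def pick() -> GeneRef:
        if rng.random() < PREF_P:
            return rng.choice(endpoint_pool)
        return rng.choice(refs)

    for k in range(n_interactions):
        subject, obj = pick(), pick()
        itype = rng.choices(types, weights=weights, k=1)[0]
        user = rng.random() < USER_SUBMITTED_FRACTION
        kb.interactions.append(
            InteractionRecord(
                record_id=k + 1,
                subject=subject,
                object=obj,
                interaction_type=itype,
                directed=itype is InteractionType.protein_dna,
                pubmed_ids=tuple(
                    sorted(
                        rng.randrange(10_000_000, 35_000_000)
                        for _ in range(rng.randint(1, 3))
                    )
                ),
                submitter=f"curator{rng.randrange(5)}" if user else None,
                annotation_status=(
                    AnnotationStatus.user_submitted if user else AnnotationStatus.curated
                ),
            )
        )
        endpoint_pool.append(subject)
        endpoint_pool.append(obj)


def degree_by_gene(kb: Knowledgebase) -> dict[int, int]:
    """Interaction degree per gene id (self-loops count twice, matching
    the usual multigraph convention)."""
    deg: dict[int, int] = {gid: 0 for gid in kb.genes}
    for rec in kb.interactions:
        deg[rec.subject.gene_id] = deg.get(rec.subject.gene_id, 0) + 1
        deg[rec.object.gene_id] = deg.get(rec.object.gene_id, 0) + 1
    return deg
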