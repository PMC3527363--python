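"""Reproducible composite experiments on synthetic knowledgebases.

The four-panel complexity study mirrors how a practitioner manages
visual complexity: the same multi-group hub query is extracted under
(all-ortholog vs single-organism) x (radius 1 vs radius 0 with
intermediates).  On corpus-shaped fixtures — a dominant, intensively
curated organism plus sparsely covered satellites, hub-heavy degrees —
node counts decrease monotonically across the panels.
"""

from __future__ import annotations

from dataclasses import dataclass

from .extract import extract
from .fixtures import TAXON_POOL, degree_by_gene, generate_fixture
from .model import Knowledgebase, QuerySpec, RadiusMode

# corpus-shaped study conditions: 3 taxa with one dominant (90/5/5),
# hub-heavy degrees, ~30% of genes in cross-taxon ortholog groups
PANEL_N_GENES = 150
PANEL_N_TAXA = 3
PANEL_N_INTERACTIONS = 600
PANEL_ORTHOLOG_FRACTION = 0.3
PANEL_TAXON_WEIGHTS = (0.9, 0.05, 0.05)


@dataclass(frozen=True)
class ComplexityPanels:
    """Node counts of the four complexity panels."""

    r1_all_orthologs: int
    r1_single_taxon: int
    r0i_all_orthologs: int
    r0i_single_taxon: int

    @property
    def monotone(self) -> bool:
        """Strictly decreasing across panels, ties allowed between the
        single-taxon radius-1 and all-ortholog intermediates panels."""
        return (
            self.r1_all_orthologs > self.r1_single_taxon
            >= self.r0i_all_orthologs > self.r0i_single_taxon
        )


def hub_two_group_query(kb: Knowledgebase, taxon: int) -> tuple:
    """The two-group, two-overlap hub query: the six highest-degree
    ortholog-grouped genes of ``taxon``, split 4+4 with the middle two
    genes shared between groups (the structure of a reprogramming-
    factor query: two published factor sets sharing two factors)."""
    degree = degree_by_gene(kb)
    candidates = sorted(
        (
            info
            for info in kb.genes.values()
            if info.tax_id == taxon and kb.homologene_id_of(info.gene_id) is not None
        ),
        key=lambda info: (-degree[info.gene_id], info.gene_id),
    )
    ids = [info.gene_id for info in candidates[:6]]
    if len(ids) < 6:
        raise ValueError("fixture has too few ortholog-grouped genes in the taxon")
    return (
        ("Query Group 1", tuple(ids[0:4])),
        ("Query Group 2", tuple(ids[2:6])),
    )


def complexity_panels(seed: int) -> ComplexityPanels:
    """Generate one corpus-shaped fixture and measure the four panels."""
    kb = generate_fixture(
        n_genes=PANEL_N_GENES,
        n_taxa=PANEL_N_TAXA,
        n_interactions=PANEL_N_INTERACTIONS,
        ortholog_fraction=PANEL_ORTHOLOG_FRACTION,
        seed=seed,
        taxon_weights=PANEL_TAXON_WEIGHTS,
    )
    taxon = TAXON_POOL[0]
    groups = hub_two_group_query(kb, taxon)
    counts = {}
    for mode in (RadiusMode.R1, RadiusMode.R0_INTERMEDIATES):
        for organism in (None, taxon):
            spec = QuerySpec(groups=groups, radius_mode=mode, organism=organism)
            counts[(mode, organism)] = len(extract(spec, kb).nodes)
    return ComplexityPanels(
        r1_all_orthologs=counts[(RadiusMode.R1, None)],
        r1_single_taxon=counts[(RadiusMode.R1, taxon)],
        r0i_all_orthologs=counts[(RadiusMode.R0_INTERMEDIATES, None)],
        r0i_single_taxon=counts[(RadiusMode.R0_INTERMEDIATES, taxon)],
    )
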