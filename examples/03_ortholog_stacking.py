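"""Ortholog stacking vs single-organism confinement.

By default a query runs across all orthologs and genes sharing a
homology group are drawn as one stacked node — provided each member's
own interaction actually appears in the graph.  Constraining to one
taxon removes foreign genes and disables stacking entirely.
"""

from interactograph import (
    QuerySpec, RadiusMode, build_partition, extract, generate_fixture,
)
from interactograph.fixtures import TAXON_POOL

kb = generate_fixture(n_genes=90, n_taxa=3, n_interactions=350,
                      ortholog_fraction=0.5, seed=2)
members = tuple(sorted(kb.genes)[:4])

spec_all = QuerySpec(groups=(("g", members),), radius_mode=RadiusMode.R1)
g_all = extract(spec_all, kb)
part_all = build_partition(g_all, kb, spec_all)
print(f"all-ortholog mode: {len(g_all.nodes)} genes, "
      f"{len(part_all.stacks)} stacks, {len(part_all.singletons)} singletons")
for stack in part_all.stacks[:5]:
    labels = [f"{kb.label_of(m)}({m.tax_id})" for m in stack.members]
    print(f"  stack hg{stack.homologene_id}: {' | '.join(labels)}")

taxon = TAXON_POOL[0]
spec_one = QuerySpec(groups=(("g", members),), radius_mode=RadiusMode.R1,
                     organism=taxon)
g_one = extract(spec_one, kb)
part_one = build_partition(g_one, kb, spec_one)
print(f"\nsingle-organism mode (taxon {taxon}): {len(g_one.nodes)} genes, "
      f"{len(part_one.stacks)} stacks (always 0), "
      f"{len(part_one.singletons)} singletons")
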