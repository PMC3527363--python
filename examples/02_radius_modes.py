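"""The four network-radius modes on one query.

Radius 0 keeps only interactions inside the query list; radius 0 with
intermediates adds outside genes touching at least two query members;
radius 1 keeps everything touching the query; radius 2 extends one more
shell.  Edge sets nest, so the counts below never decrease down the list.
"""

from interactograph import QuerySpec, RadiusMode, extract, generate_fixture

kb = generate_fixture(n_genes=120, n_taxa=2, n_interactions=500,
                      ortholog_fraction=0.3, seed=5)
members = tuple(sorted(kb.genes)[:5])
print(f"query: genes {members}\n")

for mode in (RadiusMode.R0, RadiusMode.R0_INTERMEDIATES,
             RadiusMode.R1, RadiusMode.R2):
    spec = QuerySpec(groups=(("Query Group 1", members),), radius_mode=mode)
    g = extract(spec, kb)
    roles = sorted({r.value for r in g.node_role.values()})
    print(f"radius {mode.value:>2}: {len(g.nodes):4d} genes, "
          f"{len(g.edges):4d} edges   roles: {roles}")
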