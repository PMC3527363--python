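"""Managing visual complexity: the four-panel experiment.

A hub-gene query on a corpus-shaped fixture (one dominant taxon, scale-
free degrees, cross-taxon orthologs) is extracted four ways: (all
orthologs vs single taxon) x (radius 1 vs radius 0 with intermediates).
Node counts fall from the most permissive panel to the most constrained
one — the two complexity dials a user has besides shortening the query.
"""

from interactograph import complexity_panels

panels = complexity_panels(seed=0)
print(f"radius 1, all orthologs:          {panels.r1_all_orthologs:4d} nodes")
print(f"radius 1, single taxon:           {panels.r1_single_taxon:4d} nodes")
print(f"radius 0 + intermediates, all:    {panels.r0i_all_orthologs:4d} nodes")
print(f"radius 0 + intermediates, single: {panels.r0i_single_taxon:4d} nodes")
print(f"monotone decrease: {panels.monotone}")
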