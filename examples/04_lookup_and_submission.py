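"""Gene lookup and crowdsourced curation.

The lookup tool searches descriptions, GO terms, symbols and synonyms at
once, flagging genes that already have documented interactions; its GO
hit list can seed a query group.  The submission pipeline pre-checks a
proposed interaction, warns about redundancy, commits with attribution
and supports reverting to an earlier state.
"""

from interactograph import (
    InteractionType, SubmissionProposal, generate_fixture,
    go_term_gene_list, keyword_search,
)
from interactograph.knowledgebase import serialize_state
from interactograph.submission import commit, precheck, revert_to

kb = generate_fixture(n_genes=60, n_taxa=2, n_interactions=200, seed=8)

hits = keyword_search("cardiac muscle", kb)
print(f"lookup 'cardiac muscle': {len(hits)} genes")
for h in hits[:5]:
    flag = "C" if h.supported_by_kb else "-"
    print(f"  [{flag}] gene {h.gene.gene_id} matched {sorted(h.matched_fields)}")

go_genes = go_term_gene_list("cardiac", kb)
print(f"genes GO-annotated with 'cardiac': {len(go_genes)} "
      f"(usable as a query group: {','.join(map(str, go_genes[:6]))}...)")

a, b = (kb.genes[g].gene for g in sorted(kb.genes)[:2])
proposal = SubmissionProposal(
    subject=a, object=b, interaction_type=InteractionType.protein_protein,
    directed=False, pubmed_ids=(34567890,), submitter="alice",
)
verdict = precheck(proposal, kb)
print(f"\nprecheck: {verdict.status.value}")
for msg in verdict.messages:
    print(f"  {msg}")

before = serialize_state(kb)
record_id = commit(proposal, kb, force=True, timestamp="2026-10-01T00:00:00+00:00")
print(f"committed as record {record_id}; interactions now {len(kb.interactions)}")

kb2 = revert_to(kb, 0)
print(f"revert to baseline restores prior state: "
      f"{serialize_state(kb2) == before}")
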