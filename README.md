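# interactograph

A file-backed knowledgebase of documented biomolecular interactions with
query-scoped subgraph extraction, ortholog stacking and GraphViz DOT
rendering — the engine behind "show me everything known to interact with
these genes, at a complexity I can read".

It is written for systems biologists and curators who keep interaction
knowledge in flat tables (interaction records backed by PubMed
citations, Entrez-style gene annotations, HomoloGene-style ortholog
groups) and want reproducible, clickable network drawings rather than a
database server: everything is plain TSV in, DOT text out, with a
Python API, a thin CLI and a seeded synthetic-data generator so the
whole pipeline runs without any external download.

## The model

A query is up to three named **query groups** of genes
(`"Oct4, Sox2, Klf4, Myc/Oct4, Sox2, Nanog, Lin28A"` — commas separate
genes, slashes separate groups; groups are color-coded in the drawing).
Tokens resolve with precedence *numeric Entrez ID > official symbol >
synonym*, case-insensitively, scoped to an organism when one is given;
ambiguous tokens are reported, never silently picked.

The result graph is controlled by the **network radius** *r*, a
query-scoped distance (not the graph-theoretic radius):

- **r = 0** — only interactions among the query genes;
- **r = 0 with intermediates** — additionally, every outside gene that
  interacts with ≥ 2 *distinct* query members, with its query-side
  edges (intermediate–intermediate edges are not drawn);
- **r = 1** — every interaction touching a query gene;
- **r = 2** — radius-1 plus every interaction touching a radius-1
  interactant (first-shell/first-shell edges included).

Edge direction never affects neighborhood membership but is preserved in
the drawing. Duplicate documentation of one relation (same pair, type,
direction) is merged into a single edge carrying every record id, so
each drawn edge stays traceable to its records and citations.

By default queries run **across orthologs**: each query gene is expanded
through its homology group, and orthologs are drawn as one **stacked
(compound) node** — but only members whose own interactions actually
appear in the graph may stack. Constraining to a single organism keeps
only that taxon's genes (both endpoints) and disables stacking. Nodes
are **hypernodes**: one node per gene whatever molecular role each edge
implies — a black line is a protein–protein interaction, a red arrow a
protein→DNA regulation, blue dashed a genetic interaction. A legend for
every encoding present, plus the group colors, is generated into the
document, and a URL map links nodes to gene pages and edges to
interaction records.

Around the query engine sit a **gene lookup** (case-insensitive phrase
search across descriptions, GO terms, symbols and synonyms, flagging
genes with documented interactions) and a **curation pipeline**:
proposed interactions are validated, checked against the knowledgebase
for redundancy (same pair and type; direction counts for protein→DNA),
committed with submitter attribution into an append-only history, and
revertible to any earlier state.

## Worked example

`examples/02_radius_modes.py` generates a two-taxon knowledgebase of
120 genes and 500 interactions (seed 5) and extracts the same 5-gene
query under all four radius modes:

```sh
$ python examples/02_radius_modes.py
query: genes (1001, 1002, 1003, 1004, 1005)

radius  0:    5 genes,    1 edges   roles: ['query']
radius 0i:    9 genes,   10 edges   roles: ['intermediate', 'query']
radius  1:   42 genes,   43 edges   roles: ['neighbor', 'query']
radius  2:   97 genes,  354 edges   roles: ['neighbor', 'query', 'second_shell']
```

The same 5-gene query
grows from the 1 interaction documented inside the query list to the
354-edge two-shell neighborhood — the nesting of the four modes is the
complexity dial. `examples/` contains one short script per capability
(generation + query + DOT, radius modes, ortholog stacking, lookup +
submission, the four-panel complexity experiment); each prints what it
computes and what the numbers mean.

The same pipeline from the shell:

```sh
interactograph fixture --out kb/ --n-genes 80 --n-taxa 3 --seed 11
interactograph query --kb kb/ --genes "G1001, G1005" --radius 1 --out result.dot
interactograph lookup --kb kb/ --keyword "cardiac muscle"
interactograph submit-check --kb kb/ --subject 1001 --subject-tax 9606 \
    --object 1005 --object-tax 10090 --type PP --pubmed 34567890 --submitter alice
```

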