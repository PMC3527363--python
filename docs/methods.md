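# Methods

## Data model and on-disk dialect

The knowledgebase is three data tables plus an audit log, all
tab-separated text with one header row (documented in
`interactograph/knowledgebase.py`):

- **interactions.tsv** — one documented interaction per row: two
  Entrez-style gene/taxon pairs, a type code (`PP`, `PD`, `GI`,
  `OTHER`), a direction flag (`AB` exactly for protein→DNA), one or
  more PubMed ids, an optional submitter and a curation status.
- **gene_info.tsv** — per-gene identity: official symbol (unique within
  a taxon, case-insensitively), pipe-joined synonyms, free-text
  description, pipe-joined GO term strings (opaque; no ontology
  traversal).
- **homologene.tsv** — one row per ortholog-group member; a gene
  belongs to at most one group.
- **history.tsv** — the append-only change log (sequence number,
  add/revert, record id, user, timestamp).

Writing is canonical (interactions by record id, genes by gene id,
homology rows by group/taxon/gene) so `load ∘ write` is a byte
identity, which the tests exploit as a round-trip oracle. Interacting
genes missing from gene_info are tolerated — real curation dumps have
such orphans — and labeled by raw id with a logged warning. Self-
interactions are permitted and render as self-loops. Duplicate
documentation of one relation is kept as distinct records; merging
happens at render time so provenance is never lost.

### History semantics

Two contracts pull against each other: the history must be append-only
(with an explicit `revert` action), and a commit followed by a revert
must restore the previous state byte-for-byte. Both cannot hold for
the history file itself, so state equality is defined over the three
data tables (`serialize_state`), and `revert_to` appends one
compensating `revert` event per removed record. The on-disk history
stores record ids, not full records; replaying a history whose added
records were later reverted is therefore exact in memory but not
reconstructible from a freshly loaded directory — an accepted
limitation of the flat-file audit log.

## Identifier resolution

Resolution precedence is numeric id > official symbol > synonym,
case-insensitive, restricted to the query organism when one is given.
Purely numeric tokens are always treated as gene ids (Entrez symbols
are never purely numeric in practice). When no organism is given, a
symbol or synonym matching exactly one gene across all taxa resolves;
any multi-match is reported as ambiguous with all candidates — this
relaxes the stricter "symbols require an organism" web-form rule to
"an organism is required only when the token is actually ambiguous",
which is friendlier for scripting and loses no safety. A token that is
one gene's synonym and another's official symbol resolves to the
official symbol (precedence), with the outcome visible in the
resolution report.

## Extraction

The four radius modes are implemented as predicate passes over the
filtered record list (graphs here are small enough that explicit scans
beat adjacency preprocessing, and the code stays auditable):

- r0 keeps records with both endpoints in the effective query set;
- r0-with-intermediates counts, per outside gene, its *distinct* query
  interactants (direction ignored, self-loops not counted) and admits
  the gene plus its query-side edges at ≥ 2 — two records to the same
  query gene never qualify, and ortholog-expanded query members each
  count as one member. Intermediate–intermediate edges are excluded;
- r1 keeps records touching the query set;
- r2 adds records touching any first-shell interactant, including
  first-shell/first-shell edges.

Isolated query genes stay in the graph so a user sees that a queried
gene returned nothing. Single-organism mode keeps only records with
*both* endpoints in the organism, matching the all-one-species look of
single-taxon drawings. The test suite checks every extractor against
independently written oracles (plain predicate scans and
networkx ego-graph/BFS formulations) on hundreds of random fixtures,
plus the edge-nesting chain r0 ⊆ r0i ⊆ r1 ⊆ r2.

## Ortholog stacking

Two drawn genes share a compound node iff they share a homology group
*and* each has at least one edge that appears in the drawn graph. The
second condition is the visibility rule: a gene queried but isolated
never stacks, and removing a member's last edge demotes it to a
singleton. Within-taxon paralogs sharing a group do stack — group
membership is the only grouping criterion. Stack members are ordered
by taxon id and the lowest-taxon member heads the label, giving
deterministic, species-comparable labeling. Single-organism mode
always yields all singletons.

## Rendering

DOT text is emitted directly (node order: stacks by group id then
singletons by taxon/gene; edge order: by record-id tuple), so identical
inputs give identical bytes. Encodings: protein–protein = black solid
undirected; protein→DNA = red solid arrow at the target; genetic =
blue dashed; other = gray dotted; all overridable through a flat
key=value style file, as are the colorblind-safe group palette
(Dark2), URL templates and the layout engine (default `sfdp`, written
into the document as a graph attribute). Stacks are single
record-shaped nodes, not clusters, because sfdp ignores clusters; DOT
offers no per-port URLs on record nodes, so per-member URLs are
carried in the document's URL map (`hg<group>:g<gene>` keys) while the
node itself links to its lead member. Multi-group nodes take the
lowest group's color plus a double border (`peripheries=2`). The
legend is a record-shaped node in its own cluster listing every edge
encoding present plus each query group when groups are multiple or
renamed. Record-page URLs default to a local `record://<id>` anchor
scheme since no web service is hosted; edge tooltips carry submitter
attributions for user-submitted records.

`render` writes DOT verbatim; SVG/PDF/GIF-with-image-map shell out to a
GraphViz executable and raise a named environment error when none is on
PATH.

## Synthetic data generator

`generate_fixture` emulates what the engine actually faces in curated
corpora, and is a pure function of its arguments including the seed:

- **Degree structure** — documented interaction networks are
  scale-free-like: most genes have few partners, a few hubs very many.
  Endpoints are drawn by preferential attachment (probability 0.9 of
  reusing an endpoint from the degree-weighted pool, else uniform; the
  pool is seeded with every gene once so all genes are reachable). At
  500 genes / 2000 interactions the top hub exceeds 5× the median
  degree.
- **Taxa** — genes split round-robin across a fixed pool of NCBI-style
  taxon ids, or by explicit `taxon_weights` (largest-remainder
  apportionment) to model the strong skew of real corpora toward a few
  intensively studied organisms.
- **Homology** — `ortholog_fraction` of genes enter groups of 2–3,
  drawn from distinct taxa whenever possible (within-taxon paralog
  groups arise only when taxa run out).
- **Annotations** — symbols `G<id>`; synonyms drawn from a small pool
  with deliberate collisions (so ambiguity handling is exercised);
  descriptions and GO terms sampled from a fixed domain vocabulary
  ("cardiac muscle development", "alcohol metabolic process", …) so
  phrase lookup has realistic targets.
- **Records** — type mix defaults to 60 % protein–protein, 20 %
  protein→DNA, 15 % genetic, 5 % other; ~10 % of records are
  user-submitted with a submitter name; 1–3 PubMed ids each.

What the generator does *not* emulate: literature-driven correlation
between hubness and annotation richness, taxon-specific interaction
densities, shared PubMed ids across records of one study, or realistic
symbol nomenclature. Tests passing on these fixtures therefore
establish the engine's combinatorial contracts (extraction, stacking,
filtering, rendering, curation), not biological fidelity of any
particular drawing.

## The four-panel complexity experiment

`interactograph.experiments.complexity_panels` reproduces, on synthetic
data, the standard demonstration that organism confinement and radius
reduction tame a hub query: a fixture of 150 genes across 3 taxa (gene
shares 90/5/5 — the dominant-organism shape of real corpora), 600
interactions, 30 % of genes in cross-taxon ortholog groups; the query
is the six highest-degree ortholog-grouped genes of the dominant taxon
in two groups of four sharing two genes (the published
reprogramming-factor query structure). Node counts then satisfy
n(r1, all-orthologs) > n(r1, single-taxon) ≥ n(r0i, all-orthologs) >
n(r0i, single-taxon) in ≥ 95 of 100 seeds (ties allowed at the middle
step, where the two effects are of comparable size). The dominant-taxon
skew is essential: with evenly sized taxa the single-taxon radius-1
panel is no larger than the all-ortholog intermediates panel and the
middle inequality inverts.

## Numerical and degenerate-input choices

- Node iteration is always sorted by (taxon, gene id) and edges by
  record ids: determinism everywhere, byte-identical DOT across runs.
- Empty queries, empty groups, > 3 groups and interior empty tokens are
  format errors; a trailing comma is forgiven.
- An empty include-type *or* include-status filter is rejected as a
  configuration error (either would make every query empty).
- An empty extraction result is valid (query nodes only); an empty
  graph still renders as a legend-only document.
- Problem sizes in tests and the acceptance script (fixtures ≤ 200
  genes / ≤ 800 interactions; 100–200 replicates per property) were
  chosen so the whole suite completes in seconds while still covering
  hub-dominated, multi-taxon and edge-free regimes.

## Known limitations

- Radius > 2, centrality/path analytics and interaction scoring are
  out of scope by design.
- GO terms are flat strings; no ancestor closure in lookup.
- The user registry is a plain name set; no authentication.
- PubMed ids are format-validated only; no citation retrieval.
- Re-loading a directory whose history contains reverts of records no
  longer present cannot reconstruct those records (see History
  semantics).
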