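# Methods

## Scope-aware relation model

GO's three sub-ontologies are DAGs whose edges are typed relations. For
category extraction the only property of an edge that matters is which
endpoint is *broader in semantic scope*. The package assigns every
relation one of three orientations:

* `subject_narrower` — `is_a`, `part_of`: the subject (the stanza term) is
  narrower than the object; the edge points rootward as written.
* `subject_broader` — `has_part`: "A has_part B" asserts that B occurs as
  a part of A in at least one biological instance (*part_of_some*). The
  edge is inverted at registration time, making B a child of A. This does
  **not** claim that every B is part of an A — it is a scoping statement,
  not an axiomatic one — and it keeps the graph acyclic, which is checked
  after parsing and rejected with a named cycle if violated.
* `non_scoping` — any other relation identifier. These edges are stored
  (they appear in the relation histogram) but never contribute to
  parent/child links or closures. Regulates-family relations are out of
  scope.

`allowed_relations` controls which edges are retained at all; the preset
`GO_BASIC_RELATIONS` (`is_a`, `part_of`) reproduces go-basic-style
traversal on a go-core file. Because excluding `has_part` can only remove
reachability, a category built under go-basic scoping is always a subset
of the same category under full scoping (tested as an invariant).

Ancestor/descendant closures are computed lazily per node, memoized, and
invalidated wholesale on any edge mutation — mutation after parsing is
rare, so a coarse invalidation is simpler and safe. Closures are checked
in the test suite against two independent oracles: networkx reachability
and a dense boolean-matrix transitive closure.

## OBO dialect

The parser reads the tags the method uses (`id`, `name`, `namespace`,
`def`, `is_a`, `relationship`, `is_obsolete`, `synonym`) and silently
ignores the rest (`xref`, `subset`, `alt_id`, ...). Obsolete terms are
parsed but excluded from the node index; `alt_id` merging is not
performed. Relation identifiers are normalized to snake_case. Synonyms
are stored but never used for seeding: GO has four synonym scopes of
varying reliability and many terms have none, so querying them would
weight terms unevenly.

## Category construction

Stages, in order, each run once:

1. **Seeding** — case-insensitive plain *substring* match of any keyword
   against a term's name or definition. No word-boundary logic: the
   substring rule is the method's definition, and adding boundary logic
   would silently change seeded counts.
2. **Edge recreation** — supergraph scoping edges restricted to seeded
   terms; subgraph-local parent/child maps are kept inside the `Subgraph`
   object, so the supergraph is never mutated.
3. **Representative election** — candidates are seeded terms with a
   keyword in the *name* (a definition mention is too weak to name a
   category). The candidate with the most within-subgraph descendants
   wins; ties break to the lexicographically smallest id so reruns are
   bit-identical. A lone keyword-named node with no children elects
   itself — isolated single-term concepts (an "aggresome"-style category)
   are valid. Descendant counts are taken within the seeded subgraph, not
   the supergraph, since election precedes extension. When the user
   supplies explicit seed terms, election is skipped and each seed term
   is a representative; the category's members are the union of the
   per-representative constrained subgraphs.
4. **Extension** — *comprehensive* (default, greedy): add all supergraph
   descendants of the representative; *conservative*: add only supergraph
   nodes in `ancestors(leaf) ∩ descendants(representative)` for each
   current subgraph leaf, i.e. path intermediates missed by seeding.
   Comprehensive is a superset of conservative by construction.
5. **Constraint** — members become the representative plus its
   within-subgraph descendants; every other seeded term is recorded in
   `removed_seed_ids`. Extension and constraint are not iterated to a
   fixed point; each stage runs once, in pipeline order.

## Annotation mapping

The mapping table is built at category level, not per record: category c2
is suppressed for a term t when some other category c1 also containing t
has its representative inside c2's member set (nested categories). With
`map_supersets=True` the suppression is disabled. Overlapping, non-nested
categories always keep both mappings. Duplicate representatives across
category specs are a configuration error.

GAF 2.1 records (17 tab-separated columns, `!` headers preserved) are
rewritten by substituting the GO-id column; a record mapping to several
categories yields one row per category so no assignment is lost to
downstream counting. The qualifier column — including `NOT` — is ignored
for mapping; negative annotations are therefore mapped like positive
ones, a documented limitation. Evidence filtering is opt-in (the `IEA`
exclusion preset mirrors common practice of dropping electronic
annotations); mapped + unmapped + evidence-dropped records always sum to
the input record count. Gene symbols are matched case-sensitively.

## Comparison statistics

The inclusion index `I = |S_n ∩ S_g| / |S_n|` is asymmetric: S_n is the
*non-reference* set (the other method's category), so `I = 1` states that
the other method's category is fully contained in the reference one.
Jaccard is the symmetric complement; for nested sets it equals
`|S_n|/|S_g|`. Indices are serialized to 6 significant figures. Both are
undefined (and raise) on empty inputs.

Per-gene agreement between an experimental source and a knowledgebase is
one of five mutually exclusive classes, evaluated in this order: gene
absent from the knowledgebase — or present with an empty category set,
i.e. carrying no annotation in the shared vocabulary — → *no_annotation*;
identical sets → *complete*; knowledgebase a strict superset →
*partial_superset*; non-empty intersection → *partial*; otherwise →
*none*. Per-category involvement counts are **incidences** (one tally per
gene-category pair per class), so column sums exceed gene counts by
design. Coarsening both sources through the same generic-category map
(e.g. folding centrosome and the cytoskeletal sub-compartments into
"cytoskeleton") can only merge distinctions, so the complete-agreement
count never decreases — tested as a property.

The UniProt subcellular-location controlled vocabulary is parsed from its
flat-file form (records terminated by `//`; identifier, accession,
is-a/part-of hierarchy and GO cross-reference line prefixes are
configurable via `CVDialect`). Roots are terms without parents; each root
with a GO cross-reference maps to the cross-references of itself and all
recursive children. Terms lacking a cross-reference are traversed for
connectivity but excluded from the output.

## Synthetic fixtures

The generator emulates the structures that drive seeded/added/removed
dynamics on the real ontology: keyword-named category branches under a
keyword-free global root, a configurable fraction of hierarchy edges
stated as `has_part` in the parent stanza (the same hierarchy in the
scope-inverted direction), decoy terms carrying a keyword only in their
definition, inter-category cross-links, an oversized
"macromolecular-complex-like" category containing every other branch
(superset-suppression stress), one obsolete term and one
foreign-namespace term. Ground-truth member sets are computed from the
generator's own adjacency lists — under full and under go-basic scoping —
and correspond to comprehensive extension; the categorizer plays no part
in producing them. GAF generation annotates genes to known leaf terms and
plants an exact number of unmappable records (`round(noise × records)`).

What the fixtures do **not** emulate: realistic GO term-name prose (names
are templated tokens, so keyword seeding is exact rather than noisy),
annotation-evidence heterogeneity, and the scale of a real GO release
(thousands of terms, eleven relation types). Passing tests therefore
demonstrate the correctness of the graph semantics and pipeline stages,
not retrieval quality on real curated text.

## Problem sizes and numerical choices

Default test fixtures use 2–4 categories, depth 2–4, branching 2–3
(tens to low hundreds of terms) and GAFs of 30–200 records; closure
oracle checks run on random DAGs of up to 500 nodes. These sizes exercise
every code path while keeping the whole suite in the low seconds. All
randomness is seeded; identical seeds give byte-identical fixtures and
identical pipeline output. Set outputs are unordered sets internally;
every serialized form sorts ids lexicographically.

## Known limitations

* Regulates-family and other non-scoping relations are stored inert, not
  traversed.
* `alt_id` aliases are not merged; annotations using secondary ids will
  land on the unmapped list.
* `NOT` qualifiers are ignored during mapping.
* The representative is elected before extension (pipeline order), so a
  term first reachable through extension can never become the
  representative.
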