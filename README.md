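# goslice

Slice the Gene Ontology into subgraphs representing user-defined concepts —
and use them as custom, GO-slim-like filters for gene annotations.

## The problem

Differential-abundance analyses and knowledgebase queries return gene lists
annotated with very fine-grained GO terms ("nuclear pore outer ring",
"mitochondrial intermembrane space"). Interpreting such lists usually means
binning terms into a handful of biologist-level categories ("nucleus",
"mitochondrion"). Existing routes either require a hand-curated GO slim plus
a mapping tool, or restrict themselves to the *go-basic* release because the
full *go-core* graph contains a relation — `has_part` — whose direction
points *away* from the root: "A `has_part` B" makes A the broader term, so
naive traversal across it aggregates terms into the wrong categories.

`goslice` takes only a list of keywords per category and:

1. parses go-core-style OBO text into a DAG whose every scoping edge
   (`is_a`, `part_of`, `has_part`) is oriented by semantic scope —
   `has_part` is re-read mereologically as *part_of_some* ("B is part of A
   in at least one biological instance") and inverted, so the graph remains
   a rootward-oriented DAG and the information in `has_part` edges becomes
   safely usable;
2. seeds a subgraph with every term whose name or definition contains a
   keyword, elects the seeded term with the most within-subgraph
   descendants (keyword required in the *name*) as the category
   **representative**, extends the subgraph with the representative's
   supergraph descendants (*comprehensive*) or only with nodes on
   leaf-to-representative paths (*conservative*), and finally constrains
   members to the representative's descendants — discarding serendipitous
   keyword matches;
3. maps GAF 2.x gene annotations onto the representatives (one output row
   per matching category; with *superset suppression*, a term in a nested
   category maps only to the nearest category root — a nucleolar term maps
   to "nucleolus", not also to "nucleus");
4. compares category subgraphs and per-gene annotation sets between
   methods or sources with the inclusion index
   `I = |S_n ∩ S_g| / |S_n|` (S_n the non-reference set), the Jaccard
   index `|∩| / |∪|`, and a five-way per-gene agreement classification
   (complete / partial / partial-superset / none / no-annotation).

A synthetic-fixture generator (`goslice.synth`) produces OBO ontologies and
GAFs with ground truth known by construction, so the whole pipeline is
testable without downloading a GO release.

## Worked example

Generate a fixture ontology (3 categories, 2 levels deep, 4 decoy terms
that carry a keyword only in their definition) plus a 30-record GAF with
10 % unmappable noise, then run the pipeline:

```sh
goslice fixtures --seed 7 --out-dir fx --categories 3 --depth 2 \
    --decoys 4 --genes 30 --noise 0.1
goslice create --ontology fx/fixture.obo --config categories.yaml \
    --output-dir out --namespace cellular_component
cat out/summary.tsv
```

with `categories.yaml` naming one keyword per category:

```yaml
categories:
- {name: mitochondrion, keywords: [mitochondrion]}
- {name: nucleus,       keywords: [nucleus]}
- {name: vesicle,       keywords: [vesicle]}
```

This prints (stderr log, then the summary table):

```
INFO ontology data-version: fixture/seed-7
INFO parsed 26 terms, 25 edges
category        representative  seeded  added  removed  total
mitochondrion   GO:0000009      8       0      1        7
nucleus         GO:0000002      9       0      2        7
vesicle         GO:0000016      8       0      1        7
```

Each branch has 7 genuine terms, all carrying the keyword in their names,
so seeding finds them plus the decoys; the decoys (1, 2 and 1 per
category) are *removed* at the constraint stage because they never root to
the representative, and `total = seeded + added − removed`. Mapping the
GAF through the resulting table:

```sh
goslice map --mapping out/mapping.json --gaf fx/fixture.gaf --output-dir mapped
# INFO 30 records: 27 mapped rows, 3 unmapped, 0 evidence-dropped
```

exactly the 3 planted noise records (10 % of 30) end up on the
unmapped-record audit list, and every mapped row now carries a category
representative in its GO-id column. Two membership files can then be
compared with `goslice compare a.json b.json`; for a 14-term category
fully contained in a 58-term one this prints inclusion index `1` and
Jaccard `0.241379` (= 14/58).

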