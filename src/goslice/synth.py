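"""Synthetic ontology and GAF generation with known ground truth.

Real GO releases are large downloads; every behavior of the categorizer is
instead exercised on generated OBO text whose category structure is known
*by construction*.  A fixture ontology has:

* one keyword-free global root;
* ``n_categories`` branch trees, one per keyword, where every branch node
  carries its keyword as a whole token in its *name* (so substring seeding
  finds the whole branch) and the branch root is the intended
  representative;
* child→parent edges drawn as ``is_a``/``part_of``, with a configurable
  fraction emitted instead as ``has_part`` lines in the parent stanza —
  the same hierarchy stated in the scope-inverted direction, so go-basic
  scoping (is_a/part_of only) provably misses exactly those children;
* optional *decoy* terms that mention a keyword only in their definition
  and hang off the global root: seeded by the keyword search but never
  rooted to the category, hence removed at the constraint stage;
* optional cross-links (a leaf of one branch ``part_of`` a node of
  another) producing genuinely multi-category terms;
* a "macromolecular-complex-like" mode planting one oversized category
  that contains every other branch, to stress superset suppression;
* one obsolete term and one term in a different namespace, so parsing
  filters are exercised.

Ground-truth member sets are computed from the generator's own adjacency
lists (full scoping and go-basic scoping variants) and correspond to
comprehensive extension; the categorizer never participates in producing
them.  Same seed ⇒ byte-identical output.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from typing import Optional

KEYWORD_POOL = (
    "nucleus",
    "mitochondrion",
    "vesicle",
    "ribosome",
    "golgi",
    "lysosome",
    "endosome",
    "chromosome",
    "peroxisome",
    "cytoskeleton",
    "membrane",
    "chloroplast",
)

_NAMESPACE = "cellular_component"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic ontology.

    ``depth`` levels of ``branching`` children hang under each category
    root; ``has_part_fraction`` of branch edges are stated as has_part;
    ``cross_links`` inter-category part_of edges and ``decoy_terms``
    keyword-in-definition-only decoys are added on top.
    """

    n_categories: int = 3
    depth: int = 2
    branching: int = 2
    has_part_fraction: float = 0.0
    cross_links: int = 0
    decoy_terms: int = 0
    complex_mode: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.has_part_fraction <= 1:
            raise ValueError("has_part_fraction must be in [0, 1]")
        if self.n_categories < 1 or self.n_categories > len(KEYWORD_POOL):
            raise ValueError(
                f"n_categories must be in 1..{len(KEYWORD_POOL)}"
            )
        if min(self.depth, self.cross_links, self.decoy_terms) < 0:
            raise ValueError("depth, cross_links, decoy_terms must be >= 0")
        if self.branching < 1:
            raise ValueError("branching must be >= 1")


@dataclass(frozen=True)
class CategoryTruth:
    """Ground truth for one category (comprehensive extension semantics)."""

    name: str
    keyword: str
    root_id: str
    members: frozenset  # reachable under full scoping (has_part inverted)
    members_basic: frozenset  # reachable via is_a/part_of edges only
    decoy_ids: frozenset  # seeded by keyword but outside the branch


@dataclass
class FixtureOntology:
    """Generated OBO text plus its construction-time ground truth."""

    spec: FixtureSpec
    obo_text: str
    categories: dict  # name -> CategoryTruth
    has_part_edges: tuple  # (parent_id, child_id) pairs stated as has_part
    leaf_members: dict  # name -> sorted tuple of leaf term ids

    def manifest(self) -> dict:
        return {
            "spec": {
                "n_categories": self.spec.n_categories,
                "depth": self.spec.depth,
                "branching": self.spec.branching,
                "has_part_fraction": self.spec.has_part_fraction,
                "cross_links": self.spec.cross_links,
                "decoy_terms": self.spec.decoy_terms,
                "complex_mode": self.spec.complex_mode,
                "rng_seed": self.spec.rng_seed,
            },
            "categories": {
                name: {
                    "keyword": t.keyword,
                    "root": t.root_id,
                    "members": sorted(t.members),
                    "members_basic": sorted(t.members_basic),
                    "decoys": sorted(t.decoy_ids),
                }
                for name, t in sorted(self.categories.items())
            },
            "has_part_edges": [list(e) for e in sorted(self.has_part_edges)],
        }

    def manifest_json(self) -> str:
        return json.dumps(self.manifest(), indent=1, sort_keys=True)


class _Builder:
    def __init__(self):
        self.counter = 0
        self.stanzas: dict = {}  # id -> list of (tag, value) lines, ordered
        self.children_full: dict = {}  # parent -> set of children (scope-corrected)
        self.children_basic: dict = {}
        self.has_part_edges: list = []

    def new_id(self) -> str:
        self.counter += 1
        return f"GO:{self.counter:07d}"

    def term(self, name: str, definition: str, namespace: str = _NAMESPACE,
             obsolete: bool = False) -> str:
        tid = self.new_id()
        lines = [
            ("id", tid),
            ("name", name),
            ("namespace", namespace),
            ("def", f'"{definition}" []'),
        ]
        if obsolete:
            lines.append(("is_obsolete", "true"))
        self.stanzas[tid] = lines
        return tid

    def link(self, child: str, parent: str, relation: str) -> None:
        """State a child→parent hierarchy edge using ``relation``."""
        if relation == "has_part":
            # stated in the parent stanza, scope-inverted at parse time
            self.stanzas[parent].append(("relationship", f"has_part {child}"))
            self.has_part_edges.append((parent, child))
        elif relation == "is_a":
            self.stanzas[child].append(("is_a", parent))
        else:
            self.stanzas[child].append(("relationship", f"{relation} {parent}"))
        self.children_full.setdefault(parent, set()).add(child)
        if relation != "has_part":
            self.children_basic.setdefault(parent, set()).add(child)

    def reachable(self, root: str, basic: bool = False) -> frozenset:
        adj = self.children_basic if basic else self.children_full
        seen = {root}
        stack = [root]
        while stack:
            t = stack.pop()
            for c in adj.get(t, ()):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return frozenset(seen)

    def render(self, data_version: str) -> str:
        out = [
            "format-version: 1.2",
            f"data-version: {data_version}",
            "ontology: goslice-fixture",
            "",
        ]
        for tid in sorted(self.stanzas):
            out.append("[Term]")
            out.extend(f"{tag}: {value}" for tag, value in self.stanzas[tid])
            out.append("")
        return "\n".join(out)


def generate_ontology(spec: FixtureSpec) -> FixtureOntology:
    """Build a deterministic fixture ontology for ``spec``."""
    rng = random.Random(spec.rng_seed)
    b = _Builder()

    global_root = b.term(
        "fixture cell anatomy root",
        "Synthetic root term of the fixture ontology.",
    )

    keywords = KEYWORD_POOL[: spec.n_categories]
    branch_nodes: dict = {}  # keyword -> list of (level, id)
    roots: dict = {}
    for kw in keywords:
        root = b.term(
            f"{kw} fixture branch root",
            f"Synthetic branch root of the {kw} fixture category.",
        )
        b.link(root, global_root, "is_a")
        roots[kw] = root
        level_nodes = [root]
        nodes = [(0, root)]
        for level in range(1, spec.depth + 1):
            next_level = []
            for j, parent in enumerate(
                p for p in level_nodes for _ in range(spec.branching)
            ):
                child = b.term(
                    f"fixture {kw} level{level} node{j}",
                    f"A level {level} synthetic term of the {kw} fixture branch.",
                )
                if rng.random() < spec.has_part_fraction:
                    rel = "has_part"
                else:
                    rel = rng.choice(("is_a", "part_of"))
                b.link(child, parent, rel)
                next_level.append(child)
                nodes.append((level, child))
            level_nodes = next_level
        branch_nodes[kw] = nodes

    complex_root: Optional[str] = None
    if spec.complex_mode:
        complex_root = b.term(
            "complex fixture branch root",
            "Synthetic oversized category containing every other branch.",
        )
        b.link(complex_root, global_root, "is_a")
        for kw in keywords:
            b.link(roots[kw], complex_root, "part_of")

    for _ in range(spec.cross_links):
        if spec.n_categories < 2 or spec.depth < 1:
            break
        kw_from, kw_to = rng.sample(keywords, 2)
        # a deep leaf of one branch is also part of a node of another branch
        leaf = max(branch_nodes[kw_from], key=lambda ln: (ln[0], ln[1]))[1]
        target = rng.choice(branch_nodes[kw_to])[1]
        b.link(leaf, target, "part_of")

    decoys: dict = {kw: set() for kw in keywords}
    for k in range(spec.decoy_terms):
        kw = keywords[k % len(keywords)]
        decoy = b.term(
            f"fixture decoy node{k}",
            f"A decoy term that mentions {kw} only in its definition.",
        )
        b.link(decoy, global_root, "is_a")
        decoys[kw].add(decoy)

    # parsing-filter exercise: one obsolete term, one foreign-namespace term
    b.term(
        "fixture obsolete term",
        "An obsolete synthetic term excluded from the node index.",
        obsolete=True,
    )
    b.term(
        "fixture process term",
        "A synthetic term outside the main fixture namespace.",
        namespace="biological_process",
    )

    categories = {}
    leaf_members = {}
    all_keywords = list(keywords) + (["complex"] if spec.complex_mode else [])
    all_roots = dict(roots)
    if complex_root is not None:
        all_roots["complex"] = complex_root
    for kw in all_keywords:
        root = all_roots[kw]
        members = b.reachable(root)
        categories[kw] = CategoryTruth(
            name=kw,
            keyword=kw,
            root_id=root,
            members=members,
            members_basic=b.reachable(root, basic=True),
            decoy_ids=frozenset(decoys.get(kw, ())),
        )
        leaf_members[kw] = tuple(
            sorted(t for t in members if not b.children_full.get(t))
        )

    fixture = FixtureOntology(
        spec=spec,
        obo_text=b.render(f"fixture/seed-{spec.rng_seed}"),
        categories=categories,
        has_part_edges=tuple(b.has_part_edges),
        leaf_members=leaf_members,
    )
    return fixture


@dataclass
class GafFixture:
    """Generated GAF text plus per-gene ground-truth category sets."""

    gaf_text: str
    #: gene symbol -> set of category ROOT ids its mappable records reach
    gene_truth: dict
    noise_record_count: int
    record_count: int


def generate_gaf(
    gene_count: int,
    fixture: FixtureOntology,
    noise: float = 0.0,
    rng_seed: int = 0,
    annotations_per_gene: int = 1,
) -> GafFixture:
    """Annotate synthetic genes to known leaf terms of the fixture ontology.

    Exactly ``round(noise * records)`` records get GO ids absent from the
    ontology (and hence from any mapping table); a gene whose records are
    all noise ends up with an empty truth set.
    """
    if not 0 <= noise <= 1:
        raise ValueError("noise must be in [0, 1]")
    rng = random.Random(rng_seed)
    cat_names = sorted(fixture.categories)
    leaf_of = {c: fixture.leaf_members[c] for c in cat_names}
    # category sets containing each leaf (cross-linked leaves belong to >1)
    leaf_cats: dict = {}
    for c in cat_names:
        for leaf in fixture.categories[c].members:
            leaf_cats.setdefault(leaf, set()).add(fixture.categories[c].root_id)

    records = []  # (gene, leaf_or_None)
    for i in range(gene_count):
        gene = f"GENE{i:04d}"
        for _ in range(annotations_per_gene):
            cat = rng.choice(cat_names)
            leaf = rng.choice(leaf_of[cat])
            records.append((gene, leaf))

    n_noise = round(noise * len(records))
    noise_idx = set(rng.sample(range(len(records)), n_noise))

    lines = ["!gaf-version: 2.1", "!generated-by: goslice fixture generator"]
    gene_truth: dict = {f"GENE{i:04d}": set() for i in range(gene_count)}
    for idx, (gene, leaf) in enumerate(records):
        if idx in noise_idx:
            go_id = f"GO:9{idx:06d}"
        else:
            go_id = leaf
            gene_truth[gene] |= leaf_cats[leaf]
        cols = [
            "FIX",
            f"FX{idx:05d}",
            gene,
            "",
            go_id,
            "FIX:0000001",
            "IDA",
            "",
            "C",
            f"fixture gene {gene}",
            "",
            "protein",
            "taxon:9606",
            "20160112",
            "FIX",
            "",
            "",
        ]
        lines.append("\t".join(cols))
    return GafFixture(
        gaf_text="\n".join(lines) + "\n",
        gene_truth=gene_truth,
        noise_record_count=n_noise,
        record_count=len(records),
    )
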