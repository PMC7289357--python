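"""Keyword-driven extraction of concept subgraphs.

A category is built in five stages, mirroring how a GO-slim-like concept
filter is grown out of the full ontology graph:

1. **seed** — collect every term whose name or definition contains at least
   one user keyword (case-insensitive substring; synonyms are deliberately
   never queried because their coverage across GO is uneven);
2. **recreate edges** — restrict the supergraph's scoping edges to the
   seeded set, inducing subgraph-local parent/child links;
3. **elect a representative** — among seeded terms with a keyword in the
   *name*, pick the one with the most within-subgraph descendants (ties go
   to the lexicographically smallest id, so the build is deterministic);
4. **extend** — *comprehensive* (greedy) extension adds every supergraph
   descendant of the representative; *conservative* extension adds only
   intermediate nodes on paths from subgraph leaves up to the
   representative;
5. **constrain** — keep only the representative and its within-subgraph
   descendants, discarding serendipitous keyword matches that never rooted
   to the concept.

Subgraphs never mutate the supergraph: all subgraph-local structure lives
in the :class:`Subgraph` object itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import CategorizationError, UnknownTermError
from .obo import OntologyGraph

#: extension modes
COMPREHENSIVE = "comprehensive"
CONSERVATIVE = "conservative"


@dataclass(frozen=True)
class CategorySpec:
    """User definition of one category.

    Either ``keywords`` (lowercase substrings searched in term names and
    definitions) or explicit ``seed_terms`` (term ids used directly as
    category representatives) must be given; both may be.
    """

    name: str
    keywords: tuple = ()
    seed_terms: tuple = ()
    extension_mode: str = COMPREHENSIVE

    def __post_init__(self):
        object.__setattr__(self, "keywords", tuple(k.lower() for k in self.keywords))
        object.__setattr__(self, "seed_terms", tuple(self.seed_terms))
        if not self.keywords and not self.seed_terms:
            raise ValueError(
                f"category {self.name!r}: need at least one keyword or seed term"
            )
        if self.extension_mode not in (COMPREHENSIVE, CONSERVATIVE):
            raise ValueError(f"unknown extension mode {self.extension_mode!r}")


@dataclass
class Subgraph:
    """A category subgraph wrapping (never mutating) supergraph nodes."""

    spec: CategorySpec
    supergraph: OntologyGraph
    seeded_ids: frozenset = frozenset()
    representative_ids: tuple = ()
    member_ids: frozenset = frozenset()
    removed_seed_ids: frozenset = frozenset()
    #: per-representative constrained member sets (union == member_ids)
    members_by_representative: dict = field(default_factory=dict)
    # working state: current candidate node set and subgraph-local links
    node_ids: set = field(default_factory=set)
    _parents: dict = field(default_factory=dict)
    _children: dict = field(default_factory=dict)

    # -- derived counts, mirroring a per-category summary row --------------

    @property
    def representative_id(self) -> str:
        if len(self.representative_ids) != 1:
            raise ValueError("subgraph has multiple representatives")
        return self.representative_ids[0]

    @property
    def seeded_count(self) -> int:
        return len(self.seeded_ids)

    @property
    def added_count(self) -> int:
        return len(self.member_ids - self.seeded_ids)

    @property
    def removed_count(self) -> int:
        return len(self.removed_seed_ids)

    # -- subgraph-local structure ------------------------------------------

    def refresh_links(self) -> None:
        """Re-derive subgraph-local parent/child maps from the supergraph,
        restricted to the current candidate node set."""
        ids = self.node_ids
        self._parents = {
            t: self.supergraph.nodes[t].parent_set & ids for t in ids
        }
        self._children = {
            t: self.supergraph.nodes[t].child_set & ids for t in ids
        }

    def local_descendants(self, term_id: str) -> set:
        """Descendants of ``term_id`` within the subgraph (term excluded)."""
        seen: set = set()
        stack = list(self._children.get(term_id, ()))
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(self._children.get(t, ()))
        return seen

    def local_leaves(self) -> set:
        return {t for t in self.node_ids if not self._children.get(t)}

    def to_json(self) -> dict:
        return {
            "name": self.spec.name,
            "representative": sorted(self.representative_ids),
            "members": sorted(self.member_ids),
            "seeded_count": self.seeded_count,
            "added_count": self.added_count,
            "removed_count": self.removed_count,
        }


def seed_by_keywords(graph: OntologyGraph, keywords: Sequence[str]) -> set:
    """Every non-obsolete term whose name OR definition contains at least one
    keyword as a case-insensitive substring."""
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    kws = [k.lower() for k in keywords]
    hits = set()
    for tid, node in graph.nodes.items():
        text = node.name.lower()
        definition = node.definition.lower()
        if any(kw in text or kw in definition for kw in kws):
            hits.add(tid)
    return hits


def recreate_edges(graph: OntologyGraph, seeded: Iterable[str]) -> list:
    """Scoping edges of the supergraph with both endpoints in ``seeded``."""
    ids = set(seeded)
    for tid in ids:
        if tid not in graph.nodes:
            raise UnknownTermError(f"seeded id {tid!r} not in graph")
    return [
        e
        for e in graph.edges
        if e.relation.is_scoping and e.subject_id in ids and e.object_id in ids
    ]


def select_representative(subgraph: Subgraph, keywords: Sequence[str]) -> str:
    """Elect the category-representative term.

    Candidates are subgraph nodes with at least one keyword in the NAME
    (definitions do not qualify a node to represent a category).  The
    candidate with the most within-subgraph descendants wins; ties break to
    the lexicographically smallest id.  A lone keyword-named node with no
    descendants elects itself — isolated single-term concepts are valid
    categories.
    """
    kws = [k.lower() for k in keywords]
    candidates = [
        t
        for t in subgraph.node_ids
        if any(kw in subgraph.supergraph.nodes[t].name.lower() for kw in kws)
    ]
    if not candidates:
        raise CategorizationError(
            f"category {subgraph.spec.name!r}: no candidate representative "
            "(no seeded term has a keyword in its name); add keywords or "
            "provide seed terms"
        )
    return min(candidates, key=lambda t: (-len(subgraph.local_descendants(t)), t))


def extend_comprehensive(graph: OntologyGraph, subgraph: Subgraph) -> Subgraph:
    """Greedy extension: add every supergraph descendant of each
    representative to the candidate node set."""
    for rep in subgraph.representative_ids:
        subgraph.node_ids |= graph.descendants(rep)
    subgraph.refresh_links()
    return subgraph


def extend_conservative(graph: OntologyGraph, subgraph: Subgraph) -> Subgraph:
    """Add only supergraph nodes lying on a path between a current subgraph
    leaf and a representative (ancestors(leaf) ∩ descendants(rep))."""
    additions: set = set()
    leaves = subgraph.local_leaves()
    for rep in subgraph.representative_ids:
        rep_desc = graph.descendants(rep)
        for leaf in leaves:
            additions |= graph.ancestors(leaf) & rep_desc
    subgraph.node_ids |= additions
    subgraph.refresh_links()
    return subgraph


def constrain_to_representative(subgraph: Subgraph) -> Subgraph:
    """Final constraint: members are each representative plus its
    within-subgraph descendants; every other seeded node is recorded in
    ``removed_seed_ids``."""
    by_rep = {}
    for rep in subgraph.representative_ids:
        by_rep[rep] = frozenset({rep} | subgraph.local_descendants(rep))
    members = frozenset().union(*by_rep.values()) if by_rep else frozenset()
    subgraph.members_by_representative = by_rep
    subgraph.member_ids = members
    subgraph.removed_seed_ids = frozenset(subgraph.seeded_ids - members)
    subgraph.node_ids = set(members)
    subgraph.refresh_links()
    return subgraph


def build_category(graph: OntologyGraph, spec: CategorySpec) -> Subgraph:
    """Run the full pipeline: seed → recreate edges → elect representative
    (skipped when explicit seed terms are given: each seed term IS a
    representative) → extend per mode → constrain."""
    seeded = seed_by_keywords(graph, spec.keywords) if spec.keywords else set()
    for tid in spec.seed_terms:
        if tid not in graph.nodes:
            raise UnknownTermError(f"seed term {tid!r} not in graph")
        seeded.add(tid)

    subgraph = Subgraph(spec=spec, supergraph=graph, seeded_ids=frozenset(seeded))
    subgraph.node_ids = set(seeded)
    subgraph.refresh_links()

    if spec.seed_terms:
        subgraph.representative_ids = tuple(sorted(set(spec.seed_terms)))
    else:
        subgraph.representative_ids = (select_representative(subgraph, spec.keywords),)

    if spec.extension_mode == COMPREHENSIVE:
        extend_comprehensive(graph, subgraph)
    else:
        extend_conservative(graph, subgraph)

    return constrain_to_representative(subgraph)
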