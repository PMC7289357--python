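"""OBO parsing and a scope-aware ontology DAG.

The Gene Ontology's *go-core* release contains relations that point both
toward and away from the root of the ontology.  ``is_a`` and ``part_of``
always point rootward: the subject of the edge is *narrower* in semantic
scope than the object.  ``has_part`` points the other way — the subject is
*broader* than the object ("nucleus has_part nuclear membrane").  Traversing
``has_part`` naively therefore walks *down* in scope while believing it
walks up, which is the classic source of wrong term aggregation when the
full go-core graph is used instead of go-basic.

This module re-interprets ``has_part`` mereologically as *part_of_some*
("the object is part of the subject in at least one biological instance")
by inverting its traversal direction at edge-registration time.  Every
scoping edge then induces a consistent child → parent orientation, the
graph stays a DAG, and ancestor/descendant closures computed over the
induced ``parent_set`` / ``child_set`` links are safe to use for term
categorization.

Closures are lazy: computed on first access, memoized, and invalidated
wholesale whenever an edge is added or removed.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO, Union

import networkx as nx

from .errors import GraphCycleError, OboParseError, UnknownTermError

#: orientation values for :class:`Relation`
SUBJECT_NARROWER = "subject_narrower"
SUBJECT_BROADER = "subject_broader"
NON_SCOPING = "non_scoping"

#: default scope orientation per relation identifier
DEFAULT_ORIENTATIONS = {
    "is_a": SUBJECT_NARROWER,
    "part_of": SUBJECT_NARROWER,
    "has_part": SUBJECT_BROADER,
}

#: relations used for scoping traversal by default (full go-core scoping)
DEFAULT_SCOPING_RELATIONS = frozenset(DEFAULT_ORIENTATIONS)

#: go-basic-style scoping: drop has_part entirely
GO_BASIC_RELATIONS = frozenset({"is_a", "part_of"})


def normalize_relation_id(identifier: str) -> str:
    """Normalize a relation identifier to snake_case ("part of" -> "part_of")."""
    return re.sub(r"[\s\-]+", "_", identifier.strip()).lower()


@dataclass(frozen=True)
class Relation:
    """A relation type with its semantic-scope orientation.

    ``subject_narrower`` means the subject of an edge is narrower in scope
    than the object (is_a, part_of); ``subject_broader`` the reverse
    (has_part, re-read as part_of_some); anything else is ``non_scoping``
    and never contributes to parent/child links.
    """

    identifier: str
    scope_orientation: str = NON_SCOPING

    @property
    def is_scoping(self) -> bool:
        return self.scope_orientation in (SUBJECT_NARROWER, SUBJECT_BROADER)


@dataclass
class TermNode:
    """One ontology term. ``parent_set``/``child_set`` hold term ids and are
    derived from scoping edges after orientation, never stated directly."""

    id: str
    name: str = ""
    definition: str = ""
    namespace: str = ""
    obsolete: bool = False
    synonyms: tuple = ()  # (text, scope) pairs; stored, never used for seeding
    parent_set: set = field(default_factory=set)
    child_set: set = field(default_factory=set)


@dataclass(frozen=True)
class Edge:
    """A relation instance between two terms, as stated in the source file."""

    subject_id: str
    object_id: str
    relation: Relation

    @property
    def parent_id(self) -> Optional[str]:
        """Broader endpoint after scope orientation; None for non-scoping."""
        if self.relation.scope_orientation == SUBJECT_NARROWER:
            return self.object_id
        if self.relation.scope_orientation == SUBJECT_BROADER:
            return self.subject_id
        return None

    @property
    def child_id(self) -> Optional[str]:
        """Narrower endpoint after scope orientation; None for non-scoping."""
        if self.relation.scope_orientation == SUBJECT_NARROWER:
            return self.subject_id
        if self.relation.scope_orientation == SUBJECT_BROADER:
            return self.object_id
        return None


class OntologyGraph:
    """Id-indexed DAG of :class:`TermNode` with lazy transitive closures.

    Parameters
    ----------
    allowed_relations:
        Relation identifiers whose edges are retained.  Pass
        :data:`GO_BASIC_RELATIONS` for go-basic-style scoping.
    namespace_filter:
        If given, only terms in these namespaces are indexed.
    """

    def __init__(
        self,
        allowed_relations: Iterable[str] = DEFAULT_SCOPING_RELATIONS,
        namespace_filter: Optional[Iterable[str]] = None,
    ) -> None:
        self.nodes: dict[str, TermNode] = {}
        self.edges: list[Edge] = []
        self.relation_registry: dict[str, Relation] = {}
        self.allowed_relations = frozenset(
            normalize_relation_id(r) for r in allowed_relations
        )
        self.namespace_filter = (
            frozenset(namespace_filter) if namespace_filter is not None else None
        )
        self._ancestor_cache: dict[str, frozenset] = {}
        self._descendant_cache: dict[str, frozenset] = {}

    # -- construction -----------------------------------------------------

    def register_relation(self, identifier: str) -> Relation:
        """Return the :class:`Relation` for ``identifier``, creating it with
        its default orientation (non_scoping, with a warning, when unknown)."""
        ident = normalize_relation_id(identifier)
        rel = self.relation_registry.get(ident)
        if rel is None:
            orientation = DEFAULT_ORIENTATIONS.get(ident)
            if orientation is None:
                warnings.warn(
                    f"unknown relation {ident!r}: registered as non-scoping",
                    stacklevel=2,
                )
                orientation = NON_SCOPING
            rel = Relation(ident, orientation)
            self.relation_registry[ident] = rel
        return rel

    def add_node(self, node: TermNode) -> None:
        self.nodes[node.id] = node

    def add_edge(self, subject_id: str, object_id: str, relation_id: str) -> Edge:
        """Register an edge; scoping edges update parent/child sets."""
        for tid in (subject_id, object_id):
            if tid not in self.nodes:
                raise UnknownTermError(f"edge endpoint {tid!r} not in graph")
        edge = Edge(subject_id, object_id, self.register_relation(relation_id))
        self.edges.append(edge)
        if edge.relation.is_scoping:
            self.nodes[edge.child_id].parent_set.add(edge.parent_id)
            self.nodes[edge.parent_id].child_set.add(edge.child_id)
        self._invalidate_closures()
        return edge

    def remove_edge(self, subject_id: str, object_id: str, relation_id: str) -> None:
        """Remove one matching edge and rebuild the derived link sets."""
        ident = normalize_relation_id(relation_id)
        for i, e in enumerate(self.edges):
            if (
                e.subject_id == subject_id
                and e.object_id == object_id
                and e.relation.identifier == ident
            ):
                del self.edges[i]
                break
        else:
            raise UnknownTermError(
                f"no edge {subject_id} {ident} {object_id} in graph"
            )
        self._rebuild_links()
        self._invalidate_closures()

    def _rebuild_links(self) -> None:
        for node in self.nodes.values():
            node.parent_set.clear()
            node.child_set.clear()
        for e in self.edges:
            if e.relation.is_scoping:
                self.nodes[e.child_id].parent_set.add(e.parent_id)
                self.nodes[e.parent_id].child_set.add(e.child_id)

    def _invalidate_closures(self) -> None:
        # coarse whole-cache invalidation: mutation is rare after parse
        self._ancestor_cache.clear()
        self._descendant_cache.clear()

    # -- queries ----------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, term_id: str) -> TermNode:
        try:
            return self.nodes[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term id {term_id!r}") from None

    def ancestors(self, term_id: str) -> frozenset:
        """All ids reachable by repeated parent hops (term itself excluded)."""
        return self._closure(term_id, self._ancestor_cache, "parent_set")

    def descendants(self, term_id: str) -> frozenset:
        """All ids reachable by repeated child hops (term itself excluded)."""
        return self._closure(term_id, self._descendant_cache, "child_set")

    def _closure(self, term_id: str, cache: dict, attr: str) -> frozenset:
        if term_id not in self.nodes:
            raise UnknownTermError(f"unknown term id {term_id!r}")
        hit = cache.get(term_id)
        if hit is not None:
            return hit
        seen: set[str] = set()
        stack = list(getattr(self.nodes[term_id], attr))
        while stack:
            tid = stack.pop()
            if tid in seen:
                continue
            seen.add(tid)
            stack.extend(getattr(self.nodes[tid], attr))
        result = frozenset(seen)
        cache[term_id] = result
        return result

    def leaves(self) -> frozenset:
        return frozenset(t for t, n in self.nodes.items() if not n.child_set)

    def roots(self) -> frozenset:
        return frozenset(t for t, n in self.nodes.items() if not n.parent_set)

    def ensure_acyclic(self) -> None:
        """Raise :class:`GraphCycleError` naming one cycle if the induced
        parent→child orientation is not acyclic."""
        dg = nx.DiGraph()
        dg.add_nodes_from(self.nodes)
        dg.add_edges_from(
            (e.parent_id, e.child_id) for e in self.edges if e.relation.is_scoping
        )
        try:
            cycle = nx.find_cycle(dg)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join([cycle[0][0]] + [v for _, v in cycle])
        raise GraphCycleError(f"scoping edges form a cycle: {path}")

    def summary(self) -> dict:
        """Graph summary for JSON export."""
        hist: dict[str, int] = {}
        for e in self.edges:
            hist[e.relation.identifier] = hist.get(e.relation.identifier, 0) + 1
        return {
            "term_count": len(self.nodes),
            "edge_count": len(self.edges),
            "relation_histogram": dict(sorted(hist.items())),
        }


# -- OBO parsing ----------------------------------------------------------

_QUOTED = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _unquote(value: str, line_no: int) -> str:
    m = _QUOTED.search(value)
    if m is None:
        raise OboParseError(f"line {line_no}: expected quoted string in {value!r}")
    return m.group(1).replace('\\"', '"')


def _strip_comment(value: str) -> str:
    return value.split("!", 1)[0].strip()


def _iter_lines(source: Union[str, TextIO]) -> Iterator[tuple[int, str]]:
    if isinstance(source, str):
        source = io.StringIO(source)
    for i, raw in enumerate(source, start=1):
        yield i, raw.rstrip("\n")


def parse_obo(
    source: Union[str, TextIO],
    namespace_filter: Optional[Iterable[str]] = None,
    allowed_relations: Iterable[str] = DEFAULT_SCOPING_RELATIONS,
) -> OntologyGraph:
    """Parse OBO 1.2-style text into an :class:`OntologyGraph`.

    Only the tags the categorization method reads are interpreted
    (``id``, ``name``, ``namespace``, ``def``, ``is_a``, ``relationship``,
    ``is_obsolete``, ``synonym``); everything else (xref, subset, alt_id,
    ...) is ignored.  Obsolete terms and terms outside ``namespace_filter``
    are dropped, and an edge is retained only when its relation is in
    ``allowed_relations`` and both endpoints survive filtering.

    Raises
    ------
    OboParseError
        For a ``[Term]`` stanza without an ``id``, naming the line.
    GraphCycleError
        When the scoping edges, after has_part inversion, contain a cycle.
    """
    graph = OntologyGraph(
        allowed_relations=allowed_relations, namespace_filter=namespace_filter
    )

    stanzas: list[dict] = []
    current: Optional[dict] = None
    in_term = False

    for line_no, line in _iter_lines(source):
        line = line.strip()
        if not line:
            continue
        if line.startswith("["):
            if in_term and current is not None:
                stanzas.append(current)
            in_term = line == "[Term]"
            current = {"_line": line_no} if in_term else None
            continue
        if not in_term or current is None:
            continue
        if ":" not in line:
            continue
        key, _, value = line.partition(":")
        key = key.strip()
        value = value.strip()
        if key == "id":
            current["id"] = _strip_comment(value)
        elif key == "name":
            current["name"] = value
        elif key == "namespace":
            current["namespace"] = value
        elif key == "def":
            current["definition"] = _unquote(value, line_no)
        elif key == "is_obsolete":
            current["obsolete"] = value.lower().startswith("true")
        elif key == "synonym":
            text = _unquote(value, line_no)
            tail = value[value.rfind('"') + 1 :].split()
            scope = tail[0] if tail and not tail[0].startswith("[") else ""
            current.setdefault("synonyms", []).append((text, scope))
        elif key == "is_a":
            current.setdefault("links", []).append(("is_a", _strip_comment(value)))
        elif key == "relationship":
            parts = _strip_comment(value).split()
            if len(parts) < 2:
                raise OboParseError(
                    f"line {line_no}: malformed relationship {value!r}"
                )
            current.setdefault("links", []).append((parts[0], parts[1]))
        # all other tags intentionally ignored
    if in_term and current is not None:
        stanzas.append(current)

    for st in stanzas:
        if "id" not in st:
            raise OboParseError(
                f"[Term] stanza starting at line {st['_line']} has no id"
            )

    keep = {}
    for st in stanzas:
        if st.get("obsolete", False):
            continue
        if (
            graph.namespace_filter is not None
            and st.get("namespace", "") not in graph.namespace_filter
        ):
            continue
        keep[st["id"]] = st
        graph.add_node(
            TermNode(
                id=st["id"],
                name=st.get("name", ""),
                definition=st.get("definition", ""),
                namespace=st.get("namespace", ""),
                obsolete=False,
                synonyms=tuple(st.get("synonyms", ())),
            )
        )

    for st in keep.values():
        for rel, target in st.get("links", ()):
            rel = normalize_relation_id(rel)
            if rel not in graph.allowed_relations:
                continue
            if target not in graph.nodes:
                continue  # endpoint filtered out (namespace/obsolete)
            graph.add_edge(st["id"], target, rel)

    graph.ensure_acyclic()
    return graph
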