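"""Subgraph and annotation-set comparison.

Two summary statistics compare category subgraphs produced by different
methods, treating each subgraph's members as a set:

* the **inclusion index** ``I = |S_n ∩ S_g| / |S_n|`` — the fraction of the
  *non-reference* set S_n contained in the reference set S_g.  When the
  non-reference category is fully nested in the reference one, I = 1 even
  though the sets differ greatly in size;
* the **Jaccard index** ``|∩| / |∪|`` — symmetric similarity; for nested
  sets it reduces to |S_n|/|S_g|.

Per-gene agreement between two annotation sources (an experimental
gene→category table versus a knowledgebase-derived one) is classified into
five mutually exclusive classes: complete agreement, partial agreement,
partial agreement where the knowledgebase is a strict superset, no
agreement, and no annotation in the knowledgebase at all.

The UniProt subcellular-location controlled vocabulary is parsed into the
same :class:`~goslice.mapping.MappingTable` shape so its manually curated
hierarchy can be compared against keyword-derived subgraphs: each root of
the CV hierarchy becomes a category keyed by its GO cross-reference, with
all recursive children's GO cross-references as members (xref-less terms
are traversed for connectivity but excluded from the output).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Set

import networkx as nx

from .errors import (
    ConfigurationError,
    GraphCycleError,
    OboParseError,
    UndefinedValueError,
)
from .mapping import MappingTable

#: agreement classes, in report order
COMPLETE = "complete"
PARTIAL = "partial"
PARTIAL_SUPERSET = "partial_superset"
NONE = "none"
NO_ANNOTATION = "no_annotation"
AGREEMENT_CLASSES = (COMPLETE, PARTIAL, PARTIAL_SUPERSET, NONE, NO_ANNOTATION)


def sigfig(value: float, digits: int = 6) -> float:
    """Round to ``digits`` significant figures (table serialization)."""
    return float(f"{value:.{digits}g}")


def inclusion_index(set_n: Set[str], set_g: Set[str]) -> float:
    """``|S_n ∩ S_g| / |S_n|`` with S_n the non-reference set."""
    if not set_n:
        raise UndefinedValueError("inclusion index undefined for empty S_n")
    return len(set(set_n) & set(set_g)) / len(set_n)


def jaccard_index(set_a: Set[str], set_b: Set[str]) -> float:
    """``|A ∩ B| / |A ∪ B|``."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise UndefinedValueError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


@dataclass(frozen=True)
class SetComparison:
    """One comparison row: a non-reference category versus a reference one."""

    inclusion_index: float
    jaccard_index: float
    size_n: int  # non-reference set
    size_g: int  # reference set
    intersection_size: int

    @classmethod
    def of(cls, set_n: Set[str], set_g: Set[str]) -> "SetComparison":
        return cls(
            inclusion_index=inclusion_index(set_n, set_g),
            jaccard_index=jaccard_index(set_n, set_g),
            size_n=len(set_n),
            size_g=len(set_g),
            intersection_size=len(set(set_n) & set(set_g)),
        )

    def to_row(self) -> dict:
        return {
            "inclusion_index": sigfig(self.inclusion_index),
            "jaccard_index": sigfig(self.jaccard_index),
            "size_g": self.size_g,
            "size_n": self.size_n,
        }


@dataclass
class AgreementReport:
    """Per-gene five-way agreement classification between two sources."""

    per_gene: dict = field(default_factory=dict)
    class_counts: Counter = field(default_factory=Counter)
    #: class -> Counter over experimental categories of genes in that class
    #: (incidence counts: one tally per gene-category pair, not per gene)
    category_involvement: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.per_gene)


def classify_agreement(
    experimental: Mapping[str, Set[str]],
    knowledgebase: Mapping[str, Set[str]],
) -> AgreementReport:
    """Classify every experimental gene against the knowledgebase.

    Classes (mutually exclusive, exhaustive over the experimental genes):
    absent from the knowledgebase (or present with no mapped categories)
    → ``no_annotation``; identical sets → ``complete``; knowledgebase a
    strict superset → ``partial_superset``; otherwise a non-empty
    intersection → ``partial``; disjoint → ``none``.
    """
    if not experimental:
        raise ValueError("experimental gene table is empty")
    report = AgreementReport()
    report.category_involvement = {c: Counter() for c in AGREEMENT_CLASSES}
    for gene, exp in experimental.items():
        exp = set(exp)
        if not exp:
            raise ValueError(f"gene {gene!r} has an empty experimental set")
        kb = set(knowledgebase.get(gene, ()))
        if not kb:
            cls = NO_ANNOTATION
        elif kb == exp:
            cls = COMPLETE
        elif kb > exp:
            cls = PARTIAL_SUPERSET
        elif kb & exp:
            cls = PARTIAL
        else:
            cls = NONE
        report.per_gene[gene] = cls
        report.class_counts[cls] += 1
        report.category_involvement[cls].update(exp)
    return report


def remap_generic(
    category_sets: Mapping[str, Set[str]],
    generic_map: Mapping[str, str],
) -> dict:
    """Coarsen per-gene category sets through a category→generic-category
    map (e.g. folding the cytoskeletal sub-compartments into one
    "cytoskeleton" bin).  Every observed category must be mapped."""
    observed = set().union(*map(set, category_sets.values())) if category_sets else set()
    missing = sorted(observed - set(generic_map))
    if missing:
        raise ConfigurationError(
            "generic map missing categories: " + ", ".join(missing)
        )
    return {
        gene: {generic_map[c] for c in cats} for gene, cats in category_sets.items()
    }


# -- UniProt subcellular-location controlled vocabulary -------------------


@dataclass(frozen=True)
class CVDialect:
    """Line-prefix codes of the CV flat file; defaults target the UniProt
    subcellular-location vocabulary."""

    identifier_prefixes: tuple = ("ID", "IT", "IO")
    accession_prefix: str = "AC"
    isa_prefix: str = "HI"
    partof_prefix: str = "HP"
    go_prefix: str = "GO"
    terminator: str = "//"


@dataclass
class CVTerm:
    """One controlled-vocabulary term."""

    identifier: str
    accession: str = ""
    go_xref: Optional[str] = None
    parent_ids: set = field(default_factory=set)
    child_ids: set = field(default_factory=set)


def _cv_clean(value: str) -> str:
    return value.strip().rstrip(".")


def parse_uniprot_cv(
    source: str, dialect: CVDialect = CVDialect()
) -> MappingTable:
    """Parse a UniProt-style subcellular-location CV flat file into a
    term→category :class:`MappingTable`.

    Records end with ``//``; hierarchy lines (is-a and part-of alike) name
    parent terms by identifier.  Roots are terms without parents; each root
    with a GO cross-reference becomes a category mapping to the GO xrefs of
    itself and all recursive children.  Terms without a GO xref are kept in
    the hierarchy for connectivity but never appear in the output.
    """
    terms: dict[str, CVTerm] = {}
    current: dict = {}
    records: list[dict] = []

    def flush(line_no: int) -> None:
        if not current:
            return
        if "identifier" not in current:
            raise OboParseError(
                f"CV record ending at line {line_no} has no identifier line"
            )
        records.append(dict(current))
        current.clear()

    line_no = 0
    for line_no, line in enumerate(source.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped == dialect.terminator:
            flush(line_no)
            continue
        if len(line) < 2:
            continue
        prefix, _, value = line.partition("   ")
        prefix = prefix.strip()
        if prefix in dialect.identifier_prefixes:
            current["identifier"] = _cv_clean(value)
        elif prefix == dialect.accession_prefix:
            current["accession"] = _cv_clean(value)
        elif prefix in (dialect.isa_prefix, dialect.partof_prefix):
            current.setdefault("parents", []).append(_cv_clean(value))
        elif prefix == dialect.go_prefix:
            current["go_xref"] = _cv_clean(value).split(";")[0].strip()
    flush(line_no)

    for rec in records:
        terms[rec["identifier"]] = CVTerm(
            identifier=rec["identifier"],
            accession=rec.get("accession", ""),
            go_xref=rec.get("go_xref"),
        )
    for rec in records:
        for parent in rec.get("parents", ()):
            if parent in terms:
                terms[rec["identifier"]].parent_ids.add(parent)
                terms[parent].child_ids.add(rec["identifier"])

    dg = nx.DiGraph()
    dg.add_nodes_from(terms)
    dg.add_edges_from(
        (p, t.identifier) for t in terms.values() for p in t.parent_ids
    )
    try:
        cycle = nx.find_cycle(dg)
    except nx.NetworkXNoCycle:
        pass
    else:
        path = " -> ".join([cycle[0][0]] + [v for _, v in cycle])
        raise GraphCycleError(f"CV hierarchy contains a cycle: {path}")

    roots = [t for t in terms.values() if not t.parent_ids]
    category_to_members: dict = {}
    for root in roots:
        if root.go_xref is None:
            continue
        reachable = {root.identifier} | nx.descendants(dg, root.identifier)
        members = frozenset(
            terms[t].go_xref for t in reachable if terms[t].go_xref is not None
        )
        category_to_members[root.go_xref] = members

    term_cats: dict = {}
    for cat, members in category_to_members.items():
        for m in members:
            term_cats.setdefault(m, set()).add(cat)
    return MappingTable(
        term_to_categories={t: tuple(sorted(c)) for t, c in term_cats.items()},
        category_to_members=category_to_members,
    )
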