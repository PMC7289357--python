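"""Term→category mapping tables and GAF annotation rewriting.

A finished set of category subgraphs induces two dictionaries: term id →
category-representative ids, and representative id → member ids.  By
default *superset suppression* is applied: when one category's
representative is itself a member of another category's subgraph (e.g. the
nucleolus subgraph sits inside the nucleus subgraph), terms of the inner
category map only to the inner representative — a nucleolar term maps to
"nucleolus", not to both "nucleolus" and "nucleus".  ``map_supersets=True``
disables the suppression.

GAF 2.x files are processed as tab-separated records (17 columns, "!"
header lines passed through untouched).  A record whose GO id is in the
table is rewritten once per target category; records carrying an excluded
evidence code (commonly IEA) are dropped before mapping; everything else
goes verbatim onto the unmapped audit list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .categorize import Subgraph
from .errors import ConfigurationError, GafFormatError

GAF_COLUMNS = 17

#: evidence-code preset excluding electronic annotations
IEA_PRESET = frozenset({"IEA"})


@dataclass(frozen=True)
class GafRecord:
    """One GAF 2.x annotation row (columns 1-based in field names)."""

    columns: tuple

    def __post_init__(self):
        if len(self.columns) != GAF_COLUMNS:
            raise GafFormatError(
                f"expected {GAF_COLUMNS} columns, got {len(self.columns)}"
            )

    @property
    def db_object_symbol(self) -> str:
        return self.columns[2]

    @property
    def go_id(self) -> str:
        return self.columns[4]

    @property
    def evidence_code(self) -> str:
        return self.columns[6]

    @property
    def aspect(self) -> str:
        return self.columns[8]

    @property
    def assigned_by(self) -> str:
        return self.columns[14]

    def with_go_id(self, go_id: str) -> "GafRecord":
        cols = list(self.columns)
        cols[4] = go_id
        return GafRecord(tuple(cols))

    def to_line(self) -> str:
        return "\t".join(self.columns)

    @classmethod
    def from_line(cls, line: str, line_no: Optional[int] = None) -> "GafRecord":
        cols = line.rstrip("\n").split("\t")
        if len(cols) != GAF_COLUMNS:
            where = f"line {line_no}: " if line_no is not None else ""
            raise GafFormatError(
                f"{where}expected {GAF_COLUMNS} tab-separated columns, "
                f"got {len(cols)}"
            )
        return cls(tuple(cols))


@dataclass
class MappingTable:
    """Bidirectional term↔category association.

    ``term_to_categories`` maps every member term to the sorted tuple of
    category-representative ids it belongs to; ``category_to_members`` maps
    each representative to its member id set.
    """

    term_to_categories: dict = field(default_factory=dict)
    category_to_members: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.term_to_categories)

    def to_json(self) -> dict:
        return {
            "term_to_categories": {
                t: list(c) for t, c in sorted(self.term_to_categories.items())
            },
            "category_to_members": {
                c: sorted(m) for c, m in sorted(self.category_to_members.items())
            },
        }

    @classmethod
    def from_json(cls, payload: Mapping) -> "MappingTable":
        return cls(
            term_to_categories={
                t: tuple(c) for t, c in payload["term_to_categories"].items()
            },
            category_to_members={
                c: frozenset(m) for c, m in payload["category_to_members"].items()
            },
        )

    def dumps(self) -> str:
        return json.dumps(self.to_json(), indent=1, sort_keys=True)

    @classmethod
    def loads(cls, text: str) -> "MappingTable":
        return cls.from_json(json.loads(text))


def build_mapping(
    subgraphs: Sequence[Subgraph], map_supersets: bool = False
) -> MappingTable:
    """Build a :class:`MappingTable` from finished subgraphs.

    With ``map_supersets=False`` (the default), a term belonging to both an
    inner category c1 and an outer category c2 — where c1's representative
    is itself a member of c2's subgraph — maps only to c1.  Overlap between
    non-nested categories is preserved either way.
    """
    members_by_rep: dict = {}
    for sg in subgraphs:
        for rep, members in sg.members_by_representative.items():
            if rep in members_by_rep:
                raise ConfigurationError(
                    f"representative {rep!r} defined by more than one category"
                )
            members_by_rep[rep] = frozenset(members)

    term_cats: dict = {}
    for rep, members in members_by_rep.items():
        for t in members:
            term_cats.setdefault(t, set()).add(rep)

    if not map_supersets:
        for t, cats in term_cats.items():
            suppressed = {
                c2
                for c2 in cats
                for c1 in cats
                if c1 != c2 and c1 in members_by_rep[c2]
            }
            cats -= suppressed

    table = MappingTable(
        term_to_categories={t: tuple(sorted(c)) for t, c in term_cats.items()},
        category_to_members=members_by_rep,
    )
    return table


@dataclass
class GafMappingResult:
    """Outcome of mapping one GAF through a table.

    mapped + unmapped + evidence-dropped always account for every
    non-header input record (one input record may yield several mapped
    rows when its term belongs to several categories).
    """

    mapped_lines: list
    unmapped_records: list
    evidence_dropped: int
    input_records: int

    @property
    def mapped_gaf(self) -> str:
        return "\n".join(self.mapped_lines) + ("\n" if self.mapped_lines else "")

    @property
    def unmapped_text(self) -> str:
        lines = [r.to_line() for r in self.unmapped_records]
        return "\n".join(lines) + ("\n" if lines else "")


def map_gaf(
    gaf_source: str,
    mapping: MappingTable,
    evidence_exclude: Optional[Iterable[str]] = None,
) -> GafMappingResult:
    """Rewrite a GAF so fine-grained terms become category representatives.

    Header lines ("!") pass through unchanged.  Each mappable record is
    emitted once per target category (sorted); records with excluded
    evidence codes are dropped before mapping; unmapped records are
    returned verbatim for audit.
    """
    if not mapping.term_to_categories:
        raise ValueError("mapping table is empty")
    exclude = frozenset(evidence_exclude or ())

    mapped: list = []
    unmapped: list = []
    dropped = 0
    n_records = 0
    for line_no, line in enumerate(gaf_source.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("!"):
            mapped.append(line)
            continue
        record = GafRecord.from_line(line, line_no)
        n_records += 1
        if record.evidence_code in exclude:
            dropped += 1
            continue
        cats = mapping.term_to_categories.get(record.go_id)
        if not cats:
            unmapped.append(record)
            continue
        for cat in cats:  # already sorted
            mapped.append(record.with_go_id(cat).to_line())
    return GafMappingResult(
        mapped_lines=mapped,
        unmapped_records=unmapped,
        evidence_dropped=dropped,
        input_records=n_records,
    )


def gene_category_sets(
    gaf_source: str,
    mapping: MappingTable,
    evidence_exclude: Optional[Iterable[str]] = None,
) -> dict:
    """Aggregate mapped categories per gene symbol (case-sensitive).

    Genes whose annotations are all unmapped get the empty set.
    """
    if not mapping.term_to_categories:
        raise ValueError("mapping table is empty")
    exclude = frozenset(evidence_exclude or ())
    genes: dict = {}
    for line_no, line in enumerate(gaf_source.splitlines(), start=1):
        if not line.strip() or line.startswith("!"):
            continue
        record = GafRecord.from_line(line, line_no)
        if record.evidence_code in exclude:
            continue
        cats = mapping.term_to_categories.get(record.go_id, ())
        genes.setdefault(record.db_object_symbol, set()).update(cats)
    return genes
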