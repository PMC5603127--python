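"""Readers and writers for UMLS-release-style files and auxiliary inputs.

The UMLS Metathesaurus ships as pipe-delimited "Rich Release Format" (RRF)
files: every row is ``field|field|...|`` with a trailing pipe, no quoting and
no escaping, UTF-8 encoded.  This module parses the three Metathesaurus files
the pipeline reads (MRCONSO, MRSTY, MRREL), the Semantic Network's
fully-inherited type-relation table, a semantic-group mapping, plus the plain
TSV side inputs (MeSH-indexed citation records and curation tables).

Column schemas are shipped as data (:data:`RRF_SCHEMAS`) so that miniature
fixture files may carry only the columns the pipeline actually uses; a real
release can be adapted by passing the full column list.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

TUI_PATTERN = re.compile(r"^T[0-9]{3}$")
CUI_PATTERN = re.compile(r"^C[0-9]{7}$")

#: Column schemas for the compact RRF dialect used throughout the package.
#: Fixture files carry exactly these columns; surplus columns in a fuller
#: release file are ignored positionally.
RRF_SCHEMAS: dict[str, tuple[str, ...]] = {
    "MRCONSO": ("CUI", "LAT", "ISPREF", "STR", "SAB", "SUPPRESS"),
    "MRSTY": ("CUI", "TUI", "STY"),
    "MRREL": ("CUI1", "REL", "RELA", "CUI2", "SAB"),
    "SRSTRE2": ("STY1", "RL", "STY2"),
    "SEMGROUPS": ("GRP", "GRP_NAME", "TUI", "STY_NAME"),
}


class MalformedRowError(ValueError):
    """A row does not satisfy the expected file dialect."""

    def __init__(self, message: str, path: object = None, line: int | None = None):
        detail = message
        if path is not None:
            detail += f" [{path}"
            if line is not None:
                detail += f", line {line}"
            detail += "]"
        super().__init__(detail)
        self.path = path
        self.line = line


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConceptName:
    """One MRCONSO row: a surface term attached to a concept (CUI)."""

    cui: str
    term: str
    language: str = "ENG"
    source: str = ""
    suppress: str = "N"
    is_preferred: bool = False

    def __post_init__(self) -> None:
        if not CUI_PATTERN.match(self.cui):
            raise ValueError(f"invalid CUI {self.cui!r}")


@dataclass(frozen=True)
class ConceptTypeAssignment:
    """One MRSTY row: a concept carries a semantic type (TUI)."""

    cui: str
    tui: str

    def __post_init__(self) -> None:
        if not CUI_PATTERN.match(self.cui):
            raise ValueError(f"invalid CUI {self.cui!r}")
        if not TUI_PATTERN.match(self.tui):
            raise ValueError(f"invalid TUI {self.tui!r}")


@dataclass(frozen=True)
class ConceptRelationRecord:
    """One MRREL row: a fine-grained source-vocabulary relation between CUIs.

    Per NLM convention a row reads "CUI2 has RELA to CUI1"; consumers decide
    which column is the relation's subject via an orientation flag.
    """

    cui1: str
    rel: str
    rela: str
    cui2: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.rela == "causative_agent_of" and self.cui1 == self.cui2:
            raise ValueError(f"self-loop causative_agent_of on {self.cui1}")


class TypeRelationTriple(tuple):
    """A fully-inherited Semantic Network assertion (subject, relation, object)."""

    __slots__ = ()

    def __new__(cls, subject: str, relation: str, object: str):  # noqa: A002
        return super().__new__(cls, (subject, relation, object))

    @property
    def subject(self) -> str:
        return self[0]

    @property
    def relation(self) -> str:
        return self[1]

    @property
    def object(self) -> str:  # noqa: A003
        return self[2]

    def __repr__(self) -> str:
        return f"TypeRelationTriple({self[0]!r}, {self[1]!r}, {self[2]!r})"


@dataclass
class SemanticGroupTable:
    """Coarse aggregation of semantic types into groups (e.g. DISO, CHEM)."""

    groups: dict[str, set[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def tuis(self, group_id: str) -> set[str]:
        try:
            return self.groups[group_id]
        except KeyError:
            raise KeyError(f"semantic group {group_id!r} not in table") from None

    def group_of(self, tui: str) -> str | None:
        for gid, members in self.groups.items():
            if tui in members:
                return gid
        return None

    def all_tuis(self) -> set[str]:
        out: set[str] = set()
        for members in self.groups.values():
            out |= members
        return out


@dataclass(frozen=True)
class MeshHeading:
    """A MeSH descriptor with its attached subheadings (qualifiers)."""

    descriptor: str
    qualifiers: frozenset[str] = frozenset()


@dataclass(frozen=True)
class CitationRecord:
    """A MeSH-indexed citation: PMID, publication year, headings."""

    pmid: str
    year: int
    headings: tuple[MeshHeading, ...] = ()

    def __post_init__(self) -> None:
        if not 1800 <= self.year <= 2100:
            raise ValueError(f"year {self.year} outside [1800, 2100]")


@dataclass(frozen=True)
class CurationRow:
    subject_tui: str
    relation: str
    object_tui: str
    decision: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.decision not in ("keep", "drop"):
            raise ValueError(f"decision must be keep|drop, got {self.decision!r}")


@dataclass
class CurationTable:
    """Include/exclude decisions over candidate type pairs, keyed by
    (subject_tui, relation, object_tui) in EXPO-subject normal form."""

    rows: list[CurationRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str, str], str] = {}
        for row in self.rows:
            key = (row.subject_tui, row.relation, row.object_tui)
            if key in seen and seen[key] != row.decision:
                raise ValueError(f"conflicting curation decisions for {key}")
            seen[key] = row.decision

    def decision_for(self, subject_tui: str, relation: str, object_tui: str) -> str | None:
        for row in self.rows:
            if (row.subject_tui, row.relation, row.object_tui) == (
                subject_tui,
                relation,
                object_tui,
            ):
                return row.decision
        return None


# ---------------------------------------------------------------------------
# RRF primitives
# ---------------------------------------------------------------------------


def read_rrf(
    path: str | Path,
    column_schema: Sequence[str],
    *,
    strict: bool = True,
) -> Iterator[dict[str, str]]:
    """Parse a pipe-delimited RRF file into one dict per line.

    Fields are mapped positionally onto ``column_schema``; surplus columns are
    ignored.  Field content is preserved byte-exactly after UTF-8 decoding —
    no trimming happens beyond dropping the trailing-pipe terminator.  In
    strict mode a row with fewer fields than the schema raises
    :class:`MalformedRowError` naming the line; otherwise it is skipped with
    a warning.
    """
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.endswith("|"):
                line = line[:-1]
            fields = line.split("|")
            if len(fields) < len(column_schema):
                msg = (
                    f"expected >= {len(column_schema)} fields, got {len(fields)}"
                )
                if strict:
                    raise MalformedRowError(msg, path=path, line=lineno)
                logger.warning("skipping malformed row: %s [%s:%d]", msg, path, lineno)
                continue
            yield dict(zip(column_schema, fields))


def write_rrf(
    path: str | Path,
    rows: Iterable[Sequence[str]],
) -> None:
    """Serialize rows to the RRF dialect (pipe-separated, trailing pipe)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        for row in rows:
            handle.write("|".join(str(f) for f in row) + "|\n")


# ---------------------------------------------------------------------------
# Metathesaurus readers
# ---------------------------------------------------------------------------


def read_mrconso(
    path: str | Path,
    *,
    languages: frozenset[str] | set[str] | None = frozenset({"ENG"}),
    suppress: frozenset[str] | set[str] | None = frozenset({"N"}),
    strict: bool = True,
) -> list[ConceptName]:
    """Read concept names from MRCONSO.RRF.

    Defaults keep only English, unsuppressed rows (the usual NLM subset);
    pass ``None`` for either filter to disable it.
    """
    out = []
    for row in read_rrf(path, RRF_SCHEMAS["MRCONSO"], strict=strict):
        if languages is not None and row["LAT"] not in languages:
            continue
        if suppress is not None and row["SUPPRESS"] not in suppress:
            continue
        out.append(
            ConceptName(
                cui=row["CUI"],
                term=row["STR"],
                language=row["LAT"],
                source=row["SAB"],
                suppress=row["SUPPRESS"],
                is_preferred=row["ISPREF"] == "Y",
            )
        )
    return out


def read_mrsty(path: str | Path, *, strict: bool = True) -> list[ConceptTypeAssignment]:
    """Read concept→semantic-type assignments from MRSTY.RRF (deduplicated)."""
    seen: set[tuple[str, str]] = set()
    out = []
    for row in read_rrf(path, RRF_SCHEMAS["MRSTY"], strict=strict):
        key = (row["CUI"], row["TUI"])
        if key in seen:
            continue
        seen.add(key)
        out.append(ConceptTypeAssignment(cui=row["CUI"], tui=row["TUI"]))
    return out


def read_mrrel(path: str | Path, *, strict: bool = True) -> list[ConceptRelationRecord]:
    """Read inter-concept relation rows from MRREL.RRF."""
    return [
        ConceptRelationRecord(
            cui1=row["CUI1"],
            rel=row["REL"],
            rela=row["RELA"],
            cui2=row["CUI2"],
            source=row["SAB"],
        )
        for row in read_rrf(path, RRF_SCHEMAS["MRREL"], strict=strict)
    ]


def read_type_relations(path: str | Path, *, strict: bool = True) -> set[TypeRelationTriple]:
    """Read fully-inherited type-level relations (SRSTRE2-style rows).

    Rows are ``subject TUI | relation | object TUI``.  Relation names are
    normalized to lowercase and duplicate rows collapse to one triple.
    """
    triples: set[TypeRelationTriple] = set()
    for lineno, row in enumerate(read_rrf(path, RRF_SCHEMAS["SRSTRE2"], strict=strict), 1):
        for key in ("STY1", "STY2"):
            if not TUI_PATTERN.match(row[key]):
                raise MalformedRowError(
                    f"invalid TUI {row[key]!r}", path=path, line=lineno
                )
        triples.add(TypeRelationTriple(row["STY1"], row["RL"].lower(), row["STY2"]))
    return triples


def read_semantic_groups(path: str | Path, *, strict_partition: bool = False) -> SemanticGroupTable:
    """Read a semantic-group mapping (group_id | group_name | tui | type_name).

    With ``strict_partition`` a TUI assigned to zero groups (i.e. an empty
    mapping row) raises; otherwise the table is returned as given.
    """
    table = SemanticGroupTable()
    for lineno, row in enumerate(read_rrf(path, RRF_SCHEMAS["SEMGROUPS"]), 1):
        if not TUI_PATTERN.match(row["TUI"]):
            if strict_partition:
                raise MalformedRowError(
                    f"invalid TUI {row['TUI']!r}", path=path, line=lineno
                )
            logger.warning("skipping group row with invalid TUI %r", row["TUI"])
            continue
        table.groups.setdefault(row["GRP"], set()).add(row["TUI"])
        table.names.setdefault(row["GRP"], row["GRP_NAME"])
    return table


# ---------------------------------------------------------------------------
# Citation records
# ---------------------------------------------------------------------------


def read_citations(path: str | Path, format: str = "tsv") -> list[CitationRecord]:  # noqa: A002
    """Read MeSH-indexed citation records.

    TSV dialect (canonical): one heading per row with columns
    ``pmid, year, descriptor, semicolon-joined qualifiers``; rows sharing a
    PMID aggregate into one record.  ``medline_xml`` accepts standard MEDLINE
    citation XML as a convenience.
    """
    if format == "tsv":
        return _read_citations_tsv(path)
    if format == "medline_xml":
        return _read_citations_medline(path)
    raise ValueError(f"unknown citation format {format!r}")


def _read_citations_tsv(path: str | Path) -> list[CitationRecord]:
    order: list[str] = []
    years: dict[str, int] = {}
    headings: dict[str, list[MeshHeading]] = {}
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise MalformedRowError(
                    f"expected >= 3 columns, got {len(row)}", path=path, line=lineno
                )
            pmid, year_text, descriptor = row[0], row[1], row[2]
            if not descriptor:
                raise MalformedRowError("empty descriptor", path=path, line=lineno)
            try:
                year = int(year_text)
            except ValueError:
                raise MalformedRowError(
                    f"non-numeric year {year_text!r}", path=path, line=lineno
                ) from None
            quals = frozenset(
                q.strip().lower()
                for q in (row[3].split(";") if len(row) > 3 and row[3] else [])
                if q.strip()
            )
            if pmid not in years:
                order.append(pmid)
                years[pmid] = year
                headings[pmid] = []
            headings[pmid].append(MeshHeading(descriptor=descriptor, qualifiers=quals))
    return [
        CitationRecord(pmid=p, year=years[p], headings=tuple(headings[p])) for p in order
    ]


def _read_citations_medline(path: str | Path) -> list[CitationRecord]:
    tree = etree.parse(str(path))
    records = []
    for cit in tree.iter("MedlineCitation"):
        pmid = cit.findtext("PMID", default="").strip()
        year_text = (
            cit.findtext(".//PubDate/Year")
            or cit.findtext(".//DateCompleted/Year")
            or ""
        ).strip()
        try:
            year = int(year_text)
        except ValueError:
            raise MalformedRowError(f"non-numeric year {year_text!r} for PMID {pmid}")
        heads = []
        for mh in cit.iter("MeshHeading"):
            descriptor = (mh.findtext("DescriptorName") or "").strip()
            if not descriptor:
                continue
            quals = frozenset(
                (q.text or "").strip().lower()
                for q in mh.iter("QualifierName")
                if (q.text or "").strip()
            )
            heads.append(MeshHeading(descriptor=descriptor, qualifiers=quals))
        records.append(CitationRecord(pmid=pmid, year=year, headings=tuple(heads)))
    return records


def write_citations_tsv(path: str | Path, citations: Iterable[CitationRecord]) -> None:
    """Serialize citation records to the canonical one-heading-per-row TSV."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        for cit in citations:
            for head in cit.headings:
                quals = ";".join(sorted(head.qualifiers))
                handle.write(f"{cit.pmid}\t{cit.year}\t{head.descriptor}\t{quals}\n")


# ---------------------------------------------------------------------------
# Curation tables
# ---------------------------------------------------------------------------


def read_curation(path: str | Path) -> CurationTable:
    """Read a curation TSV (subject_tui, relation, object_tui, decision, note)."""
    rows = []
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#") or row[0] == "subject_tui":
                continue
            if len(row) < 4:
                raise MalformedRowError(
                    f"expected >= 4 columns, got {len(row)}", path=path, line=lineno
                )
            rows.append(
                CurationRow(
                    subject_tui=row[0],
                    relation=row[1],
                    object_tui=row[2],
                    decision=row[3],
                    note=row[4] if len(row) > 4 else "",
                )
            )
    return CurationTable(rows=rows)


def write_curation(path: str | Path, table: CurationTable) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("subject_tui\trelation\tobject_tui\tdecision\tnote\n")
        for row in table.rows:
            handle.write(
                f"{row.subject_tui}\t{row.relation}\t{row.object_tui}\t"
                f"{row.decision}\t{row.note}\n"
            )


def preferred_names(concepts: Iterable[ConceptName]) -> dict[str, str]:
    """Resolve one display term per CUI (preferred row wins, else first seen)."""
    names: dict[str, str] = {}
    preferred: set[str] = set()
    for record in concepts:
        if record.cui not in names:
            names[record.cui] = record.term
            if record.is_preferred:
                preferred.add(record.cui)
        elif record.is_preferred and record.cui not in preferred:
            names[record.cui] = record.term
            preferred.add(record.cui)
    return names


def cui_to_tuis(assignments: Iterable[ConceptTypeAssignment]) -> dict[str, set[str]]:
    """Index semantic-type assignments by concept."""
    index: dict[str, set[str]] = {}
    for record in assignments:
        index.setdefault(record.cui, set()).add(record.tui)
    return index
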