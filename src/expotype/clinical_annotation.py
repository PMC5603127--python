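"""Exposome filtering and analysis of concept annotations in clinical notes.

Discharge summaries arrive as plain text with standoff concept annotations
(machine output in the style of MetaMap).  This module

* parses annotation tables (a documented generic TSV, plus a convenience
  reader for MetaMap's fielded MMI lines),
* filters annotations down to exposome content — kept iff the annotation
  carries an exposure semantic type or its concept is a microbe-caused
  disorder,
* segments notes into sections by the discharge-summary convention of
  uppercase headers followed by a colon,
* summarizes annotation distributions over sections and semantic types, and
* transfers curated surface terms onto a second corpus by case-insensitive
  word-boundary matching.

Offsets are 0-based, half-open, over the raw note text.
"""

from __future__ import annotations

import bisect
import csv
import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PREAMBLE = "PREAMBLE"

#: Line-initial run of >=2 characters from uppercase letters, digits, spaces,
#: slashes and hyphens, immediately followed by a colon.
DEFAULT_HEADER_PATTERN = re.compile(r"^([A-Z][A-Z0-9 /\-]+):", re.MULTILINE)

#: MetaMap semantic-type abbreviations for the types this pipeline touches.
MMI_SEMTYPE_TO_TUI = {
    "fngs": "T004",
    "virs": "T005",
    "bact": "T007",
    "acab": "T020",
    "anab": "T190",
    "cgab": "T019",
    "dsyn": "T047",
    "emod": "T050",
    "fndg": "T033",
    "inpo": "T037",
    "mobd": "T048",
    "patf": "T046",
    "aapp": "T116",
    "antb": "T195",
    "bodm": "T122",
    "clnd": "T200",
    "horm": "T125",
    "imft": "T129",
    "inch": "T197",
    "nnon": "T114",
    "orch": "T109",
    "phsu": "T121",
    "vita": "T127",
    "diap": "T060",
    "hlca": "T058",
    "lbpr": "T059",
    "topp": "T061",
    "medd": "T074",
    "inbe": "T055",
    "socb": "T054",
    "prog": "T097",
    "orgf": "T040",
}


@dataclass(frozen=True)
class ClinicalDocument:
    doc_id: str
    text: str
    sentence_spans: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        for start, end in self.sentence_spans or ():
            if not (0 <= start <= end <= len(self.text)):
                raise ValueError(
                    f"sentence span ({start}, {end}) outside document {self.doc_id}"
                )


@dataclass(frozen=True)
class SectionSpan:
    """A header-delimited section.

    ``start``/``end`` delimit the section *body* (after the header's colon);
    ``header_start`` is where the header line begins, so that
    [header_start, end) regions tile the document together with the preamble.
    """

    name: str
    start: int
    end: int
    header_start: int = -1

    def __post_init__(self) -> None:
        if self.header_start < 0:
            object.__setattr__(self, "header_start", self.start)


@dataclass(frozen=True)
class ConceptAnnotation:
    """An offset-anchored concept mention in one note."""

    doc_id: str
    start: int
    end: int
    surface: str
    cui: str
    tuis: frozenset[str] = frozenset()
    section: str | None = field(default=None, compare=False)
    status: str = field(default="machine", compare=False)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty/inverted span ({self.start}, {self.end})")


# ---------------------------------------------------------------------------
# Corpus and annotation I/O
# ---------------------------------------------------------------------------


def read_corpus(notes_dir: str | Path, pattern: str = "*.txt") -> list[ClinicalDocument]:
    """Load one document per plain-text file; doc_id is the file stem."""
    docs = []
    for path in sorted(Path(notes_dir).glob(pattern)):
        docs.append(ClinicalDocument(doc_id=path.stem, text=path.read_text(encoding="utf-8")))
    return docs


def parse_annotations(
    path: str | Path,
    dialect: str = "generic_tsv",
    documents: Iterable[ClinicalDocument] | None = None,
) -> list[ConceptAnnotation]:
    """Read machine annotations (status="machine").

    ``generic_tsv`` columns: doc_id, start, end, surface, cui, pipe-joined
    TUIs.  ``metamap_mmi`` accepts MetaMap's fielded single-line output.
    When ``documents`` are given, offsets are validated against them.
    """
    if dialect == "generic_tsv":
        annotations = _parse_generic_tsv(path)
    elif dialect == "metamap_mmi":
        annotations = _parse_mmi(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if documents is not None:
        lengths = {doc.doc_id: len(doc.text) for doc in documents}
        for ann in annotations:
            limit = lengths.get(ann.doc_id)
            if limit is not None and ann.end > limit:
                raise ValueError(
                    f"annotation ({ann.start}, {ann.end}) exceeds document "
                    f"{ann.doc_id} of length {limit}"
                )
    return annotations


def _parse_generic_tsv(path: str | Path) -> list[ConceptAnnotation]:
    out = []
    with Path(path).open(encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if not row or row[0] in ("doc_id",) or row[0].startswith("#"):
                continue
            out.append(
                ConceptAnnotation(
                    doc_id=row[0],
                    start=int(row[1]),
                    end=int(row[2]),
                    surface=row[3],
                    cui=row[4],
                    tuis=frozenset(t for t in row[5].split("|") if t),
                )
            )
    return out


def write_annotations_tsv(path: str | Path, annotations: Iterable[ConceptAnnotation]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("doc_id\tstart\tend\tsurface\tcui\ttuis\n")
        for ann in annotations:
            handle.write(
                f"{ann.doc_id}\t{ann.start}\t{ann.end}\t{ann.surface}\t"
                f"{ann.cui}\t{'|'.join(sorted(ann.tuis))}\n"
            )


_MMI_POSITION = re.compile(r"(\d+)/(\d+)")


def _parse_mmi(path: str | Path) -> list[ConceptAnnotation]:
    # MMI fields: id|MMI|score|preferred name|CUI|[semtypes]|trigger|location|
    # positional info|treecodes; positional info is start/length (possibly
    # several, comma- or semicolon-separated) — one annotation per position.
    out = []
    with Path(path).open(encoding="utf-8", newline="") as handle:
        for line in handle:
            fields = line.rstrip("\n").split("|")
            if len(fields) < 9 or fields[1] != "MMI":
                continue
            doc_id, _, _, preferred, cui, semtypes = fields[:6]
            tuis = frozenset(
                MMI_SEMTYPE_TO_TUI[abbr]
                for abbr in semtypes.strip("[]").split(",")
                if abbr in MMI_SEMTYPE_TO_TUI
            )
            trigger = fields[6]
            surface_match = re.search(r'"([^"]+)"', trigger)
            surface = surface_match.group(1) if surface_match else preferred
            for pos in _MMI_POSITION.finditer(fields[8]):
                start, length = int(pos.group(1)), int(pos.group(2))
                out.append(
                    ConceptAnnotation(
                        doc_id=doc_id,
                        start=start,
                        end=start + length,
                        surface=surface,
                        cui=cui,
                        tuis=tuis,
                    )
                )
    return out


def write_brat_ann(path: str | Path, annotations: Sequence[ConceptAnnotation]) -> None:
    """Export one document's annotations as brat standoff entity lines."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        for i, ann in enumerate(annotations, start=1):
            tag = "Exposome" if ann.status in ("kept", "curated") else "Concept"
            handle.write(f"T{i}\t{tag} {ann.start} {ann.end}\t{ann.surface}\n")


# ---------------------------------------------------------------------------
# Exposome filter
# ---------------------------------------------------------------------------


def filter_exposome(
    annotations: Iterable[ConceptAnnotation],
    expo_tuis: Iterable[str],
    microbial_cuis: Iterable[str],
) -> tuple[list[ConceptAnnotation], list[ConceptAnnotation]]:
    """Partition annotations into (kept, rejected), order preserved.

    Kept iff the annotation carries an exposure semantic type, or its concept
    is a microbe-caused disorder.
    """
    expo_tuis = frozenset(expo_tuis)
    microbial_cuis = frozenset(microbial_cuis)
    kept, rejected = [], []
    for ann in annotations:
        if ann.tuis & expo_tuis or ann.cui in microbial_cuis:
            kept.append(dataclasses.replace(ann, status="kept"))
        else:
            rejected.append(dataclasses.replace(ann, status="rejected"))
    return kept, rejected


# ---------------------------------------------------------------------------
# Section detection and assignment
# ---------------------------------------------------------------------------


def detect_sections(
    doc: ClinicalDocument,
    header_pattern: re.Pattern[str] = DEFAULT_HEADER_PATTERN,
    default_name: str = PREAMBLE,
) -> list[SectionSpan]:
    """Segment a note at uppercase-header lines.

    Each section body runs from just after its header's colon to the next
    header (or document end).  Text before the first header becomes the
    default-named section; a document without headers is one default section.
    """
    matches = list(header_pattern.finditer(doc.text))
    sections: list[SectionSpan] = []
    if not matches or matches[0].start() > 0:
        end = matches[0].start() if matches else len(doc.text)
        sections.append(SectionSpan(name=default_name, start=0, end=end, header_start=0))
    for i, match in enumerate(matches):
        end = matches[i + 1].start() if i + 1 < len(matches) else len(doc.text)
        sections.append(
            SectionSpan(
                name=match.group(1).strip(),
                start=match.end(),
                end=end,
                header_start=match.start(),
            )
        )
    return sections


def assign_sections(
    annotations: Iterable[ConceptAnnotation],
    sections: Sequence[SectionSpan],
    default_name: str = PREAMBLE,
) -> list[ConceptAnnotation]:
    """Attach to each annotation the section whose region contains its start.

    Containment uses the header-inclusive region [header_start, end) so every
    offset of the document falls in exactly one section; an annotation
    outside all regions (possible only with foreign sections) gets the
    default name and is logged.
    """
    starts = [s.header_start for s in sections]
    out = []
    for ann in annotations:
        idx = bisect.bisect_right(starts, ann.start) - 1
        if 0 <= idx < len(sections) and ann.start < sections[idx].end:
            name = sections[idx].name
        else:
            logger.warning(
                "annotation at %d in %s lies outside all sections", ann.start, ann.doc_id
            )
            name = default_name
        out.append(dataclasses.replace(ann, section=name))
    return out


# ---------------------------------------------------------------------------
# Distributions and filtering statistics
# ---------------------------------------------------------------------------


def distribution(
    annotations: Iterable[ConceptAnnotation],
    key: str = "section",
) -> pd.DataFrame:
    """Ranked count table over sections or semantic types.

    ``section`` mode counts each annotation once; ``semantic_type`` mode
    counts an annotation once per TUI it carries.  Rows are sorted by count
    descending, then lexicographically.
    """
    counts: dict[str, int] = {}
    if key == "section":
        for ann in annotations:
            label = ann.section if ann.section is not None else PREAMBLE
            counts[label] = counts.get(label, 0) + 1
    elif key == "semantic_type":
        for ann in annotations:
            for tui in ann.tuis:
                counts[tui] = counts.get(tui, 0) + 1
    else:
        raise ValueError(f"key must be section|semantic_type, got {key!r}")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(ranked, columns=[key, "count"])


def filter_reduction(machine: int, kept: int) -> float:
    """Percentage of machine annotations removed by the exposome filter."""
    if not machine > 0:
        raise ValueError("machine count must be positive")
    if not 0 <= kept <= machine:
        raise ValueError("kept count must satisfy 0 <= kept <= machine")
    return 100.0 * (machine - kept) / machine


def corpus_filter_reduction(
    per_document: Mapping[str, tuple[int, int]],
) -> tuple[dict[str, float | None], float | None]:
    """Per-document reduction percentages plus their unweighted mean.

    Documents with zero machine annotations are reported as ``None`` and
    excluded from the mean; the mean is ``None`` when no document counts.
    """
    per_doc: dict[str, float | None] = {}
    values = []
    for doc_id, (machine, kept) in per_document.items():
        if machine == 0:
            per_doc[doc_id] = None
            continue
        value = filter_reduction(machine, kept)
        per_doc[doc_id] = value
        values.append(value)
    mean = sum(values) / len(values) if values else None
    return per_doc, mean


# ---------------------------------------------------------------------------
# Term transfer to a second corpus
# ---------------------------------------------------------------------------


def transfer_terms(
    curated_terms: Mapping[str, tuple[str, Iterable[str]]] | Iterable[str],
    corpus: Iterable[ClinicalDocument],
) -> list[ConceptAnnotation]:
    """Project curated surface terms onto new documents by exact matching.

    Matching is case-insensitive and word-boundary-delimited (so "art" never
    fires inside "heart"); at a given position the longest term wins, and
    matches never overlap.  ``curated_terms`` maps each term to its
    (cui, tuis); a bare iterable of strings is accepted, yielding
    annotations without concept identity.
    """
    if isinstance(curated_terms, Mapping):
        term_info = {
            term.lower(): (cui, frozenset(tuis))
            for term, (cui, tuis) in curated_terms.items()
        }
    else:
        term_info = {term.lower(): ("", frozenset()) for term in curated_terms}
    if not term_info:
        return []
    # longest-first alternation => longest-match-first at each position
    alternation = "|".join(
        re.escape(term) for term in sorted(term_info, key=len, reverse=True)
    )
    pattern = re.compile(rf"\b(?:{alternation})\b", re.IGNORECASE)
    out = []
    for doc in corpus:
        for match in pattern.finditer(doc.text):
            cui, tuis = term_info[match.group(0).lower()]
            out.append(
                ConceptAnnotation(
                    doc_id=doc.doc_id,
                    start=match.start(),
                    end=match.end(),
                    surface=match.group(0),
                    cui=cui,
                    tuis=tuis,
                )
            )
    return out
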