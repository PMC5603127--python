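"""Literature-coverage evaluation of the derived exposome subnetwork.

Given MeSH-indexed citations, the question is whether the subnetwork's
exposure/disorder type pairs account for each citation's exposure-disease
content.  A MeSH heading qualifies as an *exposure* when (a) its descriptor
maps — via exact, case-insensitive synonym lookup — to a concept whose
semantic type fills an EXPO slot of some kept pair, and (b) the heading
carries the subheading "adverse effects" or one of its children "toxicity"
or "poisoning".  A heading qualifies as a *disease* when one of its types
fills a DISO slot.  A citation is covered when at least one
(exposure heading, disease heading) combination's type pair occurs among
the kept pairs; the relation label plays no role at coverage time.
Chronological trends aggregate the verdicts per publication year.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expo_network import ExpoDisoPair
from .umls_io import (
    CitationRecord,
    ConceptName,
    ConceptTypeAssignment,
    cui_to_tuis,
)

logger = logging.getLogger(__name__)

#: "adverse effects" plus its MeSH children; closed set, no live tree lookup.
DEFAULT_EXPOSURE_QUALIFIERS: frozenset[str] = frozenset(
    {"adverse effects", "toxicity", "poisoning"}
)


@dataclass(frozen=True)
class CoveredPair:
    expo_descriptor: str
    expo_tui: str
    diso_descriptor: str
    diso_tui: str


@dataclass(frozen=True)
class CoverageVerdict:
    pmid: str
    covered: bool
    covered_pairs: frozenset[CoveredPair]

    def __post_init__(self) -> None:
        if self.covered != bool(self.covered_pairs):
            raise ValueError("covered flag must equal non-emptiness of covered_pairs")


class DescriptorIndex:
    """Case-insensitive exact-match index from descriptor strings to TUIs.

    Built once from concept names and type assignments; an optional source
    filter restricts matching to one vocabulary (typically MeSH).
    """

    def __init__(
        self,
        names: Iterable[ConceptName],
        assignments: Iterable[ConceptTypeAssignment],
        source_filter: str | None = None,
    ):
        type_index = cui_to_tuis(assignments)
        self._term_tuis: dict[str, frozenset[str]] = {}
        buckets: dict[str, set[str]] = {}
        for record in names:
            if source_filter is not None and record.source != source_filter:
                continue
            buckets.setdefault(record.term.lower(), set()).update(
                type_index.get(record.cui, set())
            )
        self._term_tuis = {t: frozenset(v) for t, v in buckets.items()}

    def tuis_for(self, descriptor: str) -> frozenset[str]:
        return self._term_tuis.get(descriptor.lower(), frozenset())


def map_descriptor_to_tuis(
    descriptor: str,
    names: Iterable[ConceptName] | DescriptorIndex,
    assignments: Iterable[ConceptTypeAssignment] = (),
    source_filter: str | None = None,
) -> frozenset[str]:
    """Union of semantic types of concepts whose term equals the descriptor
    (case-insensitive exact match); empty when unmatched."""
    if not isinstance(names, DescriptorIndex):
        names = DescriptorIndex(names, assignments, source_filter=source_filter)
    tuis = names.tuis_for(descriptor)
    if not tuis:
        logger.debug("descriptor %r matched no concept", descriptor)
    return tuis


def pmid_coverage(
    citation: CitationRecord,
    kept_pairs: Iterable[ExpoDisoPair],
    names: Iterable[ConceptName] | DescriptorIndex,
    assignments: Iterable[ConceptTypeAssignment] = (),
    quals: frozenset[str] = DEFAULT_EXPOSURE_QUALIFIERS,
    source_filter: str | None = None,
) -> CoverageVerdict:
    """Decide whether the subnetwork covers one citation.

    The qualifier requirement is per-heading: the subheading must be attached
    to the exposure descriptor itself.
    """
    if not quals:
        raise ValueError("exposure qualifier set must be non-empty")
    index = (
        names
        if isinstance(names, DescriptorIndex)
        else DescriptorIndex(names, assignments, source_filter=source_filter)
    )
    pair_keys = {(p.expo, p.diso) for p in kept_pairs}
    expo_slots = {e for e, _ in pair_keys}
    diso_slots = {d for _, d in pair_keys}

    exposure_headings = []  # (descriptor, matching expo-slot TUIs)
    disease_headings = []
    for heading in citation.headings:
        tuis = index.tuis_for(heading.descriptor)
        if tuis & expo_slots and heading.qualifiers & quals:
            exposure_headings.append((heading.descriptor, tuis & expo_slots))
        if tuis & diso_slots:
            disease_headings.append((heading.descriptor, tuis & diso_slots))

    covered: set[CoveredPair] = set()
    for (e_desc, e_tuis), (d_desc, d_tuis) in itertools.product(
        exposure_headings, disease_headings
    ):
        for e_tui, d_tui in itertools.product(sorted(e_tuis), sorted(d_tuis)):
            if (e_tui, d_tui) in pair_keys:
                covered.add(
                    CoveredPair(
                        expo_descriptor=e_desc,
                        expo_tui=e_tui,
                        diso_descriptor=d_desc,
                        diso_tui=d_tui,
                    )
                )
    return CoverageVerdict(
        pmid=citation.pmid, covered=bool(covered), covered_pairs=frozenset(covered)
    )


def corpus_coverage(
    citations: Iterable[CitationRecord],
    kept_pairs: Iterable[ExpoDisoPair],
    names: Iterable[ConceptName] | DescriptorIndex,
    assignments: Iterable[ConceptTypeAssignment] = (),
    quals: frozenset[str] = DEFAULT_EXPOSURE_QUALIFIERS,
    source_filter: str | None = None,
) -> list[tuple[CitationRecord, CoverageVerdict]]:
    """Coverage verdicts for a whole corpus, index built once."""
    index = (
        names
        if isinstance(names, DescriptorIndex)
        else DescriptorIndex(names, assignments, source_filter=source_filter)
    )
    kept_pairs = list(kept_pairs)
    return [
        (cit, pmid_coverage(cit, kept_pairs, index, quals=quals))
        for cit in citations
    ]


def trend_summary(
    verdicts: Sequence[tuple[CitationRecord, CoverageVerdict]],
) -> pd.DataFrame:
    """Per-year trend table of the four plotted coverage series.

    Columns: ``n_pmids`` (all citations of the year), ``n_covered_pmids``,
    ``n_distinct_pairs`` (distinct covered descriptor pairs),
    ``pct_covered`` (covered/total × 100), ``mean_pairs_per_pmid``
    (covered-pair count averaged over *all* PMIDs of the year) and
    ``mean_pairs_per_covered_pmid`` (averaged over covered PMIDs only).
    """
    if not verdicts:
        return pd.DataFrame(
            columns=[
                "n_pmids",
                "n_covered_pmids",
                "n_distinct_pairs",
                "pct_covered",
                "mean_pairs_per_pmid",
                "mean_pairs_per_covered_pmid",
            ]
        )
    rows = []
    by_year: dict[int, list[tuple[CitationRecord, CoverageVerdict]]] = {}
    for cit, verdict in verdicts:
        by_year.setdefault(cit.year, []).append((cit, verdict))
    for year in sorted(by_year):
        group = by_year[year]
        n_total = len(group)
        covered = [v for _, v in group if v.covered]
        distinct_pairs = {
            (p.expo_descriptor, p.diso_descriptor)
            for v in covered
            for p in v.covered_pairs
        }
        pair_counts = [len(v.covered_pairs) for _, v in group]
        covered_pair_counts = [len(v.covered_pairs) for v in covered]
        rows.append(
            {
                "year": year,
                "n_pmids": n_total,
                "n_covered_pmids": len(covered),
                "n_distinct_pairs": len(distinct_pairs),
                "pct_covered": 100.0 * len(covered) / n_total,
                "mean_pairs_per_pmid": sum(pair_counts) / n_total,
                "mean_pairs_per_covered_pmid": (
                    sum(covered_pair_counts) / len(covered) if covered else 0.0
                ),
            }
        )
    return pd.DataFrame(rows).set_index("year")


def write_verdicts_tsv(
    path: str | Path, verdicts: Sequence[tuple[CitationRecord, CoverageVerdict]]
) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("pmid\tyear\tcovered\tn_covered_pairs\tcovered_pairs\n")
        for cit, verdict in verdicts:
            pairs = ";".join(
                sorted(
                    f"{p.expo_descriptor}[{p.expo_tui}]->{p.diso_descriptor}[{p.diso_tui}]"
                    for p in verdict.covered_pairs
                )
            )
            handle.write(
                f"{cit.pmid}\t{cit.year}\t{int(verdict.covered)}\t"
                f"{len(verdict.covered_pairs)}\t{pairs}\n"
            )
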