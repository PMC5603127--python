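"""Infer disorder concepts that imply a microbial exposure.

A disease like botulism deterministically implies prior exposure to a
pathogen (Clostridium botulinum), so a mention of the disease stands in for
the exposure itself.  Source ontologies such as SNOMED-CT encode this as the
fine-grained ``causative_agent_of`` relation between concepts.  This module
scans those relation rows for agents typed as fungus (T004), virus (T005) or
bacterium (T007) whose outcome concept belongs to the disorder semantic
group, yielding (disease, microbe) pairs with names resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .umls_io import (
    ConceptName,
    ConceptRelationRecord,
    ConceptTypeAssignment,
    cui_to_tuis,
    preferred_names,
)

logger = logging.getLogger(__name__)

#: The three semantic types representing the most common microbial exposures.
MICROBE_TUIS: frozenset[str] = frozenset({"T004", "T005", "T007"})

CAUSATIVE_AGENT_OF = "causative_agent_of"


@dataclass(frozen=True)
class MicrobialDisorder:
    """A disorder concept paired with its causative microbe concept."""

    disease_cui: str
    disease_name: str
    disease_tui: str
    microbe_cui: str
    microbe_name: str
    microbe_tui: str


def microbe_concepts(
    assignments: Iterable[ConceptTypeAssignment],
    microbe_tuis: frozenset[str] = MICROBE_TUIS,
) -> set[str]:
    """CUIs carrying at least one microbe semantic type."""
    return {a.cui for a in assignments if a.tui in microbe_tuis}


def extract_microbial_disorders(
    relations: Iterable[ConceptRelationRecord],
    assignments: Iterable[ConceptTypeAssignment],
    names: Iterable[ConceptName] | Mapping[str, str],
    diso_set: Iterable[str],
    *,
    agent_column: str = "cui2",
    microbe_tuis: frozenset[str] = MICROBE_TUIS,
    rela: str = CAUSATIVE_AGENT_OF,
    source_filter: str | None = None,
    strict: bool = True,
) -> set[MicrobialDisorder]:
    """Extract (disease, microbe) pairs from causative-agent relation rows.

    A row qualifies when its relation label equals ``rela``, the agent CUI
    carries a microbe semantic type and the outcome CUI carries at least one
    type from ``diso_set``.  Outcomes carrying multiple disorder types emit
    one record per type; records are deduplicated.  The microbe's type in
    the output is its (alphabetically first) microbe TUI.

    Per NLM convention an MRREL row reads "CUI2 has RELA to CUI1", so the
    agent defaults to ``cui2`` and the outcome to ``cui1``; pass
    ``agent_column="cui1"`` for data written in the inverse reading.
    ``source_filter`` restricts rows to one source vocabulary (e.g. the
    SNOMED-CT source abbreviation).  In strict mode a qualifying CUI without
    any name raises; permissive mode substitutes the CUI string.
    """
    if agent_column not in ("cui1", "cui2"):
        raise ValueError(f"agent_column must be cui1|cui2, got {agent_column!r}")
    assignments = list(assignments)
    type_index = cui_to_tuis(assignments)
    microbes = microbe_concepts(assignments, microbe_tuis)
    if isinstance(names, Mapping):
        name_index = dict(names)
    else:
        name_index = preferred_names(names)
    diso_set = frozenset(diso_set)

    def resolve(cui: str) -> str:
        term = name_index.get(cui)
        if term is None:
            if strict:
                raise ValueError(f"no name available for {cui}")
            logger.warning("no name for %s; using CUI as display string", cui)
            return cui
        return term

    out: set[MicrobialDisorder] = set()
    for record in relations:
        if record.rela != rela:
            continue
        if source_filter is not None and record.source != source_filter:
            continue
        agent = record.cui2 if agent_column == "cui2" else record.cui1
        outcome = record.cui1 if agent_column == "cui2" else record.cui2
        if agent not in microbes:
            continue
        outcome_diso_tuis = type_index.get(outcome, set()) & diso_set
        if not outcome_diso_tuis:
            continue
        microbe_tui = min(type_index[agent] & microbe_tuis)
        for disease_tui in outcome_diso_tuis:
            out.add(
                MicrobialDisorder(
                    disease_cui=outcome,
                    disease_name=resolve(outcome),
                    disease_tui=disease_tui,
                    microbe_cui=agent,
                    microbe_name=resolve(agent),
                    microbe_tui=microbe_tui,
                )
            )
    return out


def write_microbial_tsv(path: str | Path, records: Iterable[MicrobialDisorder]) -> None:
    """Write the six-column disorder/microbe listing."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write(
            "disease_cui\tdisease_name\tdisease_tui\t"
            "microbe_cui\tmicrobe_name\tmicrobe_tui\n"
        )
        for rec in sorted(
            records, key=lambda r: (r.disease_cui, r.microbe_cui, r.disease_tui)
        ):
            handle.write(
                f"{rec.disease_cui}\t{rec.disease_name}\t{rec.disease_tui}\t"
                f"{rec.microbe_cui}\t{rec.microbe_name}\t{rec.microbe_tui}\n"
            )


def distinct_diseases(records: Iterable[MicrobialDisorder]) -> set[str]:
    """Distinct disorder CUIs (a disease with several microbes counts once)."""
    return {rec.disease_cui for rec in records}
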