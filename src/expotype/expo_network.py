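"""Derive the exposure→disorder semantic-type subnetwork.

The method asks an event-driven question — *what nongenetic factors could
contribute to a disorder?* — and answers it by template matching over the
fully-inherited type-level relations of the Semantic Network.  The disorder
(DISO) slot of the template is filled from the DISO semantic group (minus
T050 Experimental Model of Disease, an artificial setting); four relations
are accepted, each with a fixed orientation:

    DISO is result_of EXPO
    DISO is associated_with EXPO
    EXPO causes DISO
    EXPO complicates DISO

Every matching triple yields a *candidate* exposure/disorder type pair; a
curation table (include/exclude decisions, stored as data) then partitions
candidates into kept and dropped.  Kept pairs are exported as TSV and as
DOT/GraphML graphs colored by semantic group.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .umls_io import (
    CurationTable,
    SemanticGroupTable,
    TypeRelationTriple,
)

logger = logging.getLogger(__name__)

DISO_IS_SUBJECT = "diso_is_subject"
EXPO_IS_SUBJECT = "expo_is_subject"

#: The four printed relations with their orientations: for result_of and
#: associated_with the disorder type is the relation's subject; for causes
#: and complicates the exposure type is.
DEFAULT_RELATION_SPECS: tuple[tuple[str, str], ...] = (
    ("result_of", DISO_IS_SUBJECT),
    ("associated_with", DISO_IS_SUBJECT),
    ("causes", EXPO_IS_SUBJECT),
    ("complicates", EXPO_IS_SUBJECT),
)

#: Disorder semantic group id and the excluded artificial-setting type.
DISORDER_GROUP = "DISO"
EXPERIMENTAL_MODEL_TUI = "T050"


@dataclass(frozen=True)
class ExposureEventTemplate:
    """DISO-slot types plus the relation/orientation specs to match."""

    diso_types: frozenset[str]
    relation_specs: tuple[tuple[str, str], ...] = DEFAULT_RELATION_SPECS

    def __post_init__(self) -> None:
        if not self.relation_specs:
            raise ValueError("relation_specs must be non-empty")
        for _, orientation in self.relation_specs:
            if orientation not in (DISO_IS_SUBJECT, EXPO_IS_SUBJECT):
                raise ValueError(f"invalid orientation {orientation!r}")


@dataclass(frozen=True)
class ExpoDisoPair:
    """A normalized exposure-type / disorder-type edge of the subnetwork.

    The pair is stored in EXPO/DISO slot form with the original relation name
    and orientation retained, so "DISO result_of EXPO" and "EXPO causes DISO"
    coexist without double counting.  ``status`` is excluded from identity so
    curation can relabel a pair without changing set membership.
    """

    expo: str
    relation: str
    diso: str
    orientation: str
    status: str = field(default="candidate", compare=False)

    def with_status(self, status: str) -> "ExpoDisoPair":
        if self.status != "candidate" or status not in ("kept", "dropped"):
            raise ValueError(
                f"illegal status transition {self.status!r} -> {status!r}"
            )
        return dataclasses.replace(self, status=status)


@dataclass
class CurationOutcome:
    kept: set[ExpoDisoPair]
    dropped: set[ExpoDisoPair]
    unmatched_rows: list


def diso_types(
    groups: SemanticGroupTable,
    *,
    disorder_group: str = DISORDER_GROUP,
    exclude: Iterable[str] = (EXPERIMENTAL_MODEL_TUI,),
) -> frozenset[str]:
    """The disorder group's semantic types, minus the excluded ones (T050)."""
    if disorder_group not in groups.groups:
        raise KeyError(
            f"semantic-group table has no {disorder_group!r} group; "
            f"groups present: {sorted(groups.groups)}"
        )
    return frozenset(groups.tuis(disorder_group)) - frozenset(exclude)


def match_exposure_template(
    triples: Iterable[TypeRelationTriple],
    template: ExposureEventTemplate,
) -> set[ExpoDisoPair]:
    """Emit a candidate pair for every triple matching a relation spec.

    A triple matches a spec when its relation name equals the spec's and the
    participant in the DISO slot (subject or object, per orientation) is one
    of the template's disorder types; the other participant fills the EXPO
    slot.  A type may appear in both slots across different pairs.
    """
    specs = {}
    for relation, orientation in template.relation_specs:
        specs.setdefault(relation, []).append(orientation)
    candidates: set[ExpoDisoPair] = set()
    for triple in triples:
        for orientation in specs.get(triple.relation, ()):
            if orientation == DISO_IS_SUBJECT:
                diso, expo = triple.subject, triple.object
            else:
                expo, diso = triple.subject, triple.object
            if diso in template.diso_types:
                candidates.add(
                    ExpoDisoPair(
                        expo=expo,
                        relation=triple.relation,
                        diso=diso,
                        orientation=orientation,
                    )
                )
    return candidates


def apply_curation(
    candidates: Iterable[ExpoDisoPair],
    curation: CurationTable,
    default: str = "drop",
) -> CurationOutcome:
    """Partition candidates into kept and dropped per the curation table.

    Curation rows are keyed (subject=EXPO tui, relation, object=DISO tui) in
    normalized slot form.  Candidates without a matching row get ``default``
    ("drop" mirrors the keep-only-verified stance; "keep" is the exploratory
    mode).  Curation rows matching no candidate are returned for logging.
    """
    if default not in ("keep", "drop"):
        raise ValueError(f"default must be keep|drop, got {default!r}")
    decisions = {
        (row.subject_tui, row.relation, row.object_tui): row.decision
        for row in curation.rows
    }
    matched_keys: set[tuple[str, str, str]] = set()
    kept: set[ExpoDisoPair] = set()
    dropped: set[ExpoDisoPair] = set()
    for cand in candidates:
        key = (cand.expo, cand.relation, cand.diso)
        decision = decisions.get(key)
        if decision is not None:
            matched_keys.add(key)
        else:
            decision = default
        if decision == "keep":
            kept.add(cand.with_status("kept"))
        else:
            dropped.add(cand.with_status("dropped"))
    unmatched = [
        row
        for row in curation.rows
        if (row.subject_tui, row.relation, row.object_tui) not in matched_keys
    ]
    for row in unmatched:
        logger.info(
            "curation row (%s, %s, %s) matched no candidate",
            row.subject_tui,
            row.relation,
            row.object_tui,
        )
    return CurationOutcome(kept=kept, dropped=dropped, unmatched_rows=unmatched)


def exposure_types(pairs: Iterable[ExpoDisoPair]) -> frozenset[str]:
    """Distinct EXPO-slot semantic types over the kept pairs."""
    return frozenset(pair.expo for pair in pairs)


def disorder_slot_types(pairs: Iterable[ExpoDisoPair]) -> frozenset[str]:
    """Distinct DISO-slot semantic types over the kept pairs."""
    return frozenset(pair.diso for pair in pairs)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

_GROUP_COLORS = {
    "CHEM": "#2ca02c",  # Chemicals & Drugs — green
    "PROC": "#9467bd",  # Procedures — purple
    "ACTI": "#3f51b5",  # Activities & Behaviors — indigo
    "DISO": "#d62728",
    "DEVI": "#8c564b",
    "LIVB": "#ff7f0e",
    "PHYS": "#17becf",
}
_DEFAULT_COLOR = "#7f7f7f"


def build_graph(
    pairs: Iterable[ExpoDisoPair],
    groups: SemanticGroupTable,
    focus: str | None = None,
) -> nx.MultiDiGraph:
    """Build the directed type network, optionally restricted to the ego
    neighborhood of ``focus``.

    Edges keep the printed orientation: result_of/associated_with point
    outward from the disorder node; causes/complicates point from the
    exposure node toward the disorder.
    """
    selected = [
        p for p in pairs if focus is None or focus in (p.expo, p.diso)
    ]
    if focus is not None and not selected:
        logger.warning("focus type %s occurs in no pair; graph is empty", focus)
    graph = nx.MultiDiGraph()
    for pair in sorted(selected, key=lambda p: (p.expo, p.relation, p.diso)):
        for tui in (pair.expo, pair.diso):
            if tui not in graph:
                gid = groups.group_of(tui)
                graph.add_node(
                    tui,
                    group=gid or "",
                    group_name=groups.names.get(gid, "") if gid else "",
                    color=_GROUP_COLORS.get(gid, _DEFAULT_COLOR),
                )
        if pair.orientation == DISO_IS_SUBJECT:
            graph.add_edge(pair.diso, pair.expo, relation=pair.relation)
        else:
            graph.add_edge(pair.expo, pair.diso, relation=pair.relation)
    return graph


def export_network(
    pairs: Iterable[ExpoDisoPair],
    groups: SemanticGroupTable,
    out_prefix: str | Path,
    focus: str | None = None,
) -> dict[str, Path]:
    """Write the network as DOT and GraphML; returns the written paths."""
    graph = build_graph(pairs, groups, focus=focus)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    dot_path = out_prefix.with_suffix(".dot")
    graphml_path = out_prefix.with_suffix(".graphml")
    _write_dot(graph, dot_path)
    nx.write_graphml(graph, graphml_path, named_key_ids=True)
    return {"dot": dot_path, "graphml": graphml_path}


def _write_dot(graph: nx.MultiDiGraph, path: Path) -> None:
    # minimal DOT serialization: node color by semantic group, edge label by
    # relation; identifiers are TUIs so no quoting edge cases arise
    lines = ["digraph exposome {"]
    for node, data in sorted(graph.nodes(data=True)):
        lines.append(
            f'  {node} [style=filled, fillcolor="{data.get("color", _DEFAULT_COLOR)}", '
            f'group="{data.get("group", "")}"];'
        )
    for u, v, data in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1], e[2]["relation"])):
        lines.append(f'  {u} -> {v} [label="{data["relation"]}"];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Pair TSV round-trip (Supplement-style kept-pair listing)
# ---------------------------------------------------------------------------


def write_pairs_tsv(path: str | Path, pairs: Iterable[ExpoDisoPair]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("expo_tui\trelation\tdiso_tui\torientation\n")
        for pair in sorted(pairs, key=lambda p: (p.expo, p.relation, p.diso)):
            handle.write(
                f"{pair.expo}\t{pair.relation}\t{pair.diso}\t{pair.orientation}\n"
            )


def read_pairs_tsv(path: str | Path, status: str = "kept") -> set[ExpoDisoPair]:
    pairs: set[ExpoDisoPair] = set()
    with Path(path).open(encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if not row or row[0] in ("expo_tui",) or row[0].startswith("#"):
                continue
            pairs.add(
                ExpoDisoPair(
                    expo=row[0],
                    relation=row[1],
                    diso=row[2],
                    orientation=row[3],
                    status=status,
                )
            )
    return pairs
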