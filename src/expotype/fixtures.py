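"""Self-contained miniature inputs for every pipeline stage.

Real UMLS releases are licensed, clinical notes are access-restricted and a
dated PubMed snapshot cannot be redistributed, so this module generates
synthetic stand-ins carrying their own ground truth:

* a miniature UMLS-like release (MRCONSO/MRSTY/MRREL/SRSTRE2/semantic
  groups) that embeds the printed microbe-disease relations and
  exposure-disease MeSH examples plus adversarial distractors generated
  near the decision boundaries (microbe agent with non-disorder outcome,
  disorder outcome with non-microbe agent, wrong relation label,
  suppressed or non-English synonyms);
* synthetic sectioned discharge-summary-style notes with planted exposome
  and background concept mentions at recorded offsets;
* synthetic MeSH citation corpora with a planted coverage rate and per-PMID
  truth labels.

All outputs are deterministic: an identical :class:`FixtureSpec` (same seed)
produces byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .expo_network import ExpoDisoPair
from .umls_io import CurationRow, CurationTable, write_curation, write_rrf

# ---------------------------------------------------------------------------
# Printed reference data
# ---------------------------------------------------------------------------

#: Example disorder concepts of microbial etiology:
#: (disease_cui, disease_name, disease_tui, microbe_cui, microbe_name,
#: microbe_tui).  The Leptospira microbe CUI is C0023358.
MICROBIAL_DISORDER_EXAMPLES: tuple[tuple[str, str, str, str, str, str], ...] = (
    ("C0006057", "Botulism", "T037", "C0009055", "Clostridium botulinum", "T007"),
    ("C0275677", "Miscarriage due to Leptospira", "T046", "C0023358", "Leptospira", "T007"),
    ("C0376618", "Endotoxemia", "T033", "C0018150", "Gram-negative bacteria", "T007"),
    ("C0266024", "Moon's molar teeth", "T019", "C0040840", "Treponema pallidum", "T007"),
    ("C0032768", "Postherpetic neuralgia", "T047", "C0042338", "Human herpesvirus 3", "T005"),
    ("C0032371", "Poliomyelitis", "T047", "C0206435", "Human poliovirus", "T005"),
    ("C1535939", "Pneumocystis jiroveci pneumonia", "T047", "C0320385", "Pneumocystis jiroveci", "T004"),
    ("C0029307", "Oroya Fever", "T047", "C0318324", "Bartonella bacilliformis", "T007"),
)

#: Example covered exposure-disease MeSH pairs:
#: (pmid, year, exposure descriptor, exposure TUIs, disease descriptor,
#: disease TUIs).
COVERED_CITATION_EXAMPLES: tuple[tuple[str, int, str, tuple[str, ...], str, tuple[str, ...]], ...] = (
    ("20736205", 2010, "Anti-Arrhythmia Agents", ("T121",), "Hallucinations", ("T048",)),
    ("11337626", 2001, "Osteotomy", ("T061",), "Kyphosis", ("T190",)),
    ("11387778", 2001, "Colonoscopy", ("T060",), "Intestinal Perforation", ("T047",)),
    ("11581058", 2001, "Prostheses and Implants", ("T074",), "Lacrimal Duct Obstruction", ("T190",)),
    ("11747288", 2001, "HIV Protease Inhibitors", ("T121",), "Lipodystrophy", ("T047",)),
    ("11984961", 2002, "Dental Restoration, Permanent", ("T122",), "Systemic Inflammatory Response Syndrome", ("T047",)),
    ("12043843", 2002, "Haloperidol", ("T109", "T121"), "Basal Ganglia Diseases", ("T047",)),
    ("12106934", 2002, "Cardiac Catheterization", ("T058",), "Arteriovenous Fistula", ("T190",)),
)

TUI_NAMES: dict[str, str] = {
    "T004": "Fungus",
    "T005": "Virus",
    "T007": "Bacterium",
    "T019": "Congenital Abnormality",
    "T020": "Acquired Abnormality",
    "T033": "Finding",
    "T037": "Injury or Poisoning",
    "T039": "Physiologic Function",
    "T040": "Organism Function",
    "T046": "Pathologic Function",
    "T047": "Disease or Syndrome",
    "T048": "Mental or Behavioral Dysfunction",
    "T049": "Cell or Molecular Dysfunction",
    "T050": "Experimental Model of Disease",
    "T052": "Activity",
    "T054": "Social Behavior",
    "T055": "Individual Behavior",
    "T056": "Daily or Recreational Activity",
    "T058": "Health Care Activity",
    "T059": "Laboratory Procedure",
    "T060": "Diagnostic Procedure",
    "T061": "Therapeutic or Preventive Procedure",
    "T074": "Medical Device",
    "T075": "Research Device",
    "T097": "Professional or Occupational Group",
    "T098": "Population Group",
    "T109": "Organic Chemical",
    "T114": "Nucleic Acid, Nucleoside, or Nucleotide",
    "T116": "Amino Acid, Peptide, or Protein",
    "T121": "Pharmacologic Substance",
    "T122": "Biomedical or Dental Material",
    "T125": "Hormone",
    "T127": "Vitamin",
    "T129": "Immunologic Factor",
    "T131": "Hazardous or Poisonous Substance",
    "T184": "Sign or Symptom",
    "T190": "Anatomical Abnormality",
    "T191": "Neoplastic Process",
    "T195": "Antibiotic",
    "T197": "Inorganic Chemical",
    "T200": "Clinical Drug",
}

SEMANTIC_GROUPS: dict[str, tuple[str, tuple[str, ...]]] = {
    "ACTI": ("Activities & Behaviors", ("T052", "T054", "T055", "T056")),
    "CHEM": (
        "Chemicals & Drugs",
        ("T109", "T114", "T116", "T121", "T122", "T125", "T127", "T129", "T131", "T195", "T197", "T200"),
    ),
    "DEVI": ("Devices", ("T074", "T075")),
    "DISO": (
        "Disorders",
        ("T019", "T020", "T033", "T037", "T046", "T047", "T048", "T049", "T050", "T184", "T190", "T191"),
    ),
    "LIVB": ("Living Beings", ("T004", "T005", "T007", "T097", "T098")),
    "PHYS": ("Physiology", ("T039", "T040")),
    "PROC": ("Procedures", ("T058", "T059", "T060", "T061")),
}

#: Fully-inherited type-relation rows planted in the fixture SRSTRE2.
#: The first block yields the curated exposure→disorder pairs; the drop-row
#: (T019 associated_with T040) is a candidate the curation excludes; the rest
#: never match the event template (wrong relation, non-disorder slot, or the
#: excluded experimental-model type T050).
TYPE_RELATION_ROWS: tuple[tuple[str, str, str], ...] = (
    ("T048", "result_of", "T121"),
    ("T190", "result_of", "T061"),
    ("T047", "result_of", "T060"),
    ("T190", "associated_with", "T074"),
    ("T121", "causes", "T047"),
    ("T122", "causes", "T047"),
    ("T109", "causes", "T047"),
    ("T058", "complicates", "T190"),
    ("T020", "result_of", "T061"),
    ("T121", "causes", "T020"),
    ("T020", "associated_with", "T055"),
    ("T019", "associated_with", "T040"),  # candidate; curation drops it
    ("T050", "result_of", "T061"),        # experimental model: never a DISO slot
    ("T047", "isa", "T046"),
    ("T061", "affects", "T047"),
    ("T109", "causes", "T059"),           # object not a disorder type
    ("T007", "part_of", "T005"),
)

#: Curation decisions over the candidate pairs (EXPO-subject normal form).
CURATION_ROWS: tuple[tuple[str, str, str, str, str], ...] = (
    ("T121", "result_of", "T048", "keep", "drug-induced mental dysfunction"),
    ("T061", "result_of", "T190", "keep", "procedure-induced anatomical abnormality"),
    ("T060", "result_of", "T047", "keep", "diagnostic-procedure complication"),
    ("T074", "associated_with", "T190", "keep", "device-associated abnormality"),
    ("T121", "causes", "T047", "keep", "drug-induced disease"),
    ("T122", "causes", "T047", "keep", "material-induced disease"),
    ("T109", "causes", "T047", "keep", "chemical-induced disease"),
    ("T058", "complicates", "T190", "keep", "healthcare-activity complication"),
    ("T061", "result_of", "T020", "keep", "procedure-acquired abnormality"),
    ("T121", "causes", "T020", "keep", "drug-acquired abnormality"),
    ("T055", "associated_with", "T020", "keep", "behavior-associated abnormality"),
    ("T040", "associated_with", "T019", "drop", "organism function is not a qualified exposure type"),
)

#: MeSH-style descriptor concepts for the citation corpora: (descriptor,
#: cui, tuis).  CUIs above C09 are synthetic; the descriptors themselves are
#: the printed examples plus extras so every exposure/disorder slot has at
#: least one descriptor.
MESH_DESCRIPTORS: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("Anti-Arrhythmia Agents", "C0900001", ("T121",)),
    ("Osteotomy", "C0900002", ("T061",)),
    ("Colonoscopy", "C0900003", ("T060",)),
    ("Prostheses and Implants", "C0900004", ("T074",)),
    ("HIV Protease Inhibitors", "C0900005", ("T121",)),
    ("Dental Restoration, Permanent", "C0900006", ("T122",)),
    ("Haloperidol", "C0900007", ("T109", "T121")),
    ("Cardiac Catheterization", "C0900008", ("T058",)),
    ("Hallucinations", "C0900011", ("T048",)),
    ("Kyphosis", "C0900012", ("T190",)),
    ("Intestinal Perforation", "C0900013", ("T047",)),
    ("Lacrimal Duct Obstruction", "C0900014", ("T190",)),
    ("Lipodystrophy", "C0900015", ("T047",)),
    ("Systemic Inflammatory Response Syndrome", "C0900016", ("T047",)),
    ("Basal Ganglia Diseases", "C0900017", ("T047",)),
    ("Arteriovenous Fistula", "C0900018", ("T190",)),
    ("Acquired Limb Deformity", "C0900019", ("T020",)),  # synthetic descriptor
    ("Tobacco Smoking", "C0900020", ("T055",)),          # synthetic descriptor
    ("Humans", "C0900021", ("T098",)),
    ("Risk Factors", "C0900022", ("T033",)),
)

#: Section headers sampled by the note generator (printed section names).
SECTION_NAMES: tuple[str, ...] = (
    "HOSPITAL COURSE",
    "HISTORY OF PRESENT ILLNESS",
    "DISCHARGE MEDICATIONS",
    "MEDICATIONS ON ADMISSION",
    "MEDICATIONS ON DISCHARGE",
    "MEDICATIONS",
    "PAST MEDICAL HISTORY",
    "SOCIAL HISTORY",
    "ALLERGIES",
    "MEDICATIONS ON TRANSFER",
    "HOSPITAL COURSE BY SYSTEM",
    "ADMISSION MEDICATIONS",
    "RELEVANT LABORATORY DATA",
    "LABORATORY DATA",
    "HOSPITAL COURSE AND TREATMENT",
    "HOSPITALIZATION COURSE",
    "PHYSICAL EXAMINATION",
    "PAST SURGICAL HISTORY",
    "IDENTIFYING DATA",
    "DISCHARGE INSTRUCTIONS",
    "BRIEF HOSPITAL COURSE",
    "PERTINENT RESULTS",
    "SOCIAL HISTORY AND FAMILY HISTORY",
    "MAJOR SURGICAL OR INVASIVE PROCEDURE",
)

#: Note-corpus vocabulary: exposome-qualifying mentions (exposure semantic
#: types or microbe-caused disorder concepts) vs background clinical
#: concepts the filter should reject.  CUIs above C09 are synthetic.
EXPOSOME_VOCABULARY: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("haloperidol", "C0900007", ("T109", "T121")),
    ("colonoscopy", "C0900003", ("T060",)),
    ("osteotomy", "C0900002", ("T061",)),
    ("cardiac catheterization", "C0900008", ("T058",)),
    ("aspirin", "C0900031", ("T109", "T121")),
    ("lisinopril", "C0900032", ("T109", "T121")),
    ("pacemaker", "C0900033", ("T074",)),
    ("tobacco smoking", "C0900020", ("T055",)),
    ("postherpetic neuralgia", "C0032768", ("T047",)),  # microbe-caused disorder
    ("poliomyelitis", "C0032371", ("T047",)),           # microbe-caused disorder
)

BACKGROUND_VOCABULARY: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("diabetes mellitus", "C0900041", ("T047",)),
    ("hypertension", "C0900042", ("T047",)),
    ("chest pain", "C0900043", ("T184",)),
    ("shortness of breath", "C0900044", ("T033",)),
    ("sodium", "C0900045", ("T197",)),
    ("hemoglobin", "C0900046", ("T116",)),
    ("cocaine use", "C0900047", ("T048",)),
    ("domestic violence", "C0900048", ("T048",)),
    ("renal function", "C0900049", ("T040",)),
)

_FILLER_WORDS = (
    "patient", "remained", "stable", "overnight", "and", "was", "noted", "to",
    "be", "afebrile", "throughout", "the", "stay", "tolerating", "a", "regular",
    "diet", "ambulating", "without", "difficulty", "plan", "reviewed", "at",
    "length", "during", "rounds", "course", "otherwise", "uneventful", "no",
    "acute", "events", "monitored", "closely", "on", "telemetry", "followup",
    "arranged", "as", "outpatient", "values", "trended", "toward", "baseline",
    "status", "improved", "gradually", "over", "several", "days",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible recipe for one fixture set.

    ``exposome_rate`` is the probability that a planted note mention is an
    exposome-qualifying concept; its default emulates the observed clinical
    corpus condition that roughly 78% of machine annotations are non-exposome
    and get filtered out.  ``planted_coverage_rate`` plays the analogous role
    for citation corpora (the observed literature coverage sat near 90%).
    """

    seed: int = 0
    n_notes: int = 50
    n_citations: int = 1000
    planted_coverage_rate: float = 0.9
    exposome_rate: float = 0.22
    mentions_per_note: int = 24
    n_distractors: int = 30
    year_range: tuple[int, int] = (2001, 2010)
    include_reference_tables: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_coverage_rate <= 1.0:
            raise ValueError("planted_coverage_rate must be within [0, 1]")
        if not 0.0 <= self.exposome_rate <= 1.0:
            raise ValueError("exposome_rate must be within [0, 1]")


# ---------------------------------------------------------------------------
# UMLS-like release fixture
# ---------------------------------------------------------------------------


def make_umls_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a miniature UMLS-style release into ``out_dir``.

    With ``include_reference_tables`` the files embed every reference concept: the
    eight causative-agent relations, the exposure/disease MeSH descriptor
    examples and the type-relation rows behind the curated pair set.  Seeded
    distractor rows are added around each filter's decision boundary.
    Returns the written paths keyed by logical name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    conso: list[tuple[str, str, str, str, str, str]] = []  # CUI,LAT,ISPREF,STR,SAB,SUPPRESS
    sty: list[tuple[str, str, str]] = []
    rel: list[tuple[str, str, str, str, str]] = []  # CUI1,REL,RELA,CUI2,SAB
    sty_seen: set[tuple[str, str]] = set()

    def add_concept(cui: str, term: str, tuis: Iterable[str], source: str = "SNOMEDCT_US") -> None:
        conso.append((cui, "ENG", "Y", term, source, "N"))
        for tui in tuis:
            if (cui, tui) not in sty_seen:
                sty_seen.add((cui, tui))
                sty.append((cui, tui, TUI_NAMES.get(tui, "")))

    if spec.include_reference_tables:
        for d_cui, d_name, d_tui, m_cui, m_name, m_tui in MICROBIAL_DISORDER_EXAMPLES:
            add_concept(d_cui, d_name, (d_tui,))
            add_concept(m_cui, m_name, (m_tui,))
            rel.append((d_cui, "RO", "causative_agent_of", m_cui, "SNOMEDCT_US"))
        for descriptor, cui, tuis in MESH_DESCRIPTORS:
            add_concept(cui, descriptor, tuis, source="MSH")
        # synonym / suppression / language distractor rows for the first
        # disease concept: synonym matching must survive these
        conso.append(("C0006057", "ENG", "N", "Botulinum poisoning", "MSH", "N"))
        conso.append(("C0006057", "ENG", "N", "Botulism suppressed alias", "SNOMEDCT_US", "Y"))
        conso.append(("C0006057", "SPA", "N", "Botulismo", "SCTSPA", "N"))

    # adversarial distractor relations near the microbial-etiology boundary
    diso_pool = sorted(SEMANTIC_GROUPS["DISO"][1])
    non_diso_pool = ("T059", "T061", "T116", "T197", "T098")
    for i in range(spec.n_distractors):
        cui_a = f"C2{i:06d}"
        cui_b = f"C3{i:06d}"
        mode = i % 5
        if mode == 0:  # non-microbe agent with disorder outcome
            add_concept(cui_a, f"nonmicrobial agent {i}", (rng.choice(("T047", "T116", "T197")),))
            add_concept(cui_b, f"distractor disorder {i}", (rng.choice(diso_pool),))
            rel.append((cui_b, "RO", "causative_agent_of", cui_a, "SNOMEDCT_US"))
        elif mode == 1:  # microbe agent with non-disorder outcome
            add_concept(cui_a, f"distractor microbe {i}", (rng.choice(("T004", "T005", "T007")),))
            add_concept(cui_b, f"non-disorder outcome {i}", (rng.choice(non_diso_pool),))
            rel.append((cui_b, "RO", "causative_agent_of", cui_a, "SNOMEDCT_US"))
        elif mode == 2:  # microbe + disorder but the wrong relation label
            add_concept(cui_a, f"distractor microbe {i}", (rng.choice(("T004", "T005", "T007")),))
            add_concept(cui_b, f"distractor disorder {i}", (rng.choice(diso_pool),))
            rel.append((cui_b, "RO", "has_finding_site", cui_a, "SNOMEDCT_US"))
        elif mode == 3:  # outcome typed as experimental model of disease only
            add_concept(cui_a, f"distractor microbe {i}", (rng.choice(("T004", "T005", "T007")),))
            add_concept(cui_b, f"experimental model {i}", ("T050",))
            rel.append((cui_b, "RO", "causative_agent_of", cui_a, "SNOMEDCT_US"))
        else:  # hierarchical noise between microbes
            add_concept(cui_a, f"distractor microbe {i}", (rng.choice(("T004", "T005", "T007")),))
            add_concept(cui_b, f"parent microbe {i}", (rng.choice(("T004", "T005", "T007")),))
            rel.append((cui_b, "CHD", "isa", cui_a, "SNOMEDCT_US"))

    paths = {
        "mrconso": out_dir / "MRCONSO.RRF",
        "mrsty": out_dir / "MRSTY.RRF",
        "mrrel": out_dir / "MRREL.RRF",
        "srstre2": out_dir / "SRSTRE2",
        "semgroups": out_dir / "SemGroups.txt",
        "curation": out_dir / "curation.tsv",
        "reference_citations": out_dir / "reference_citations.tsv",
    }
    write_rrf(paths["mrconso"], conso)
    write_rrf(paths["mrsty"], sty)
    write_rrf(paths["mrrel"], rel)
    write_rrf(
        paths["srstre2"],
        TYPE_RELATION_ROWS if spec.include_reference_tables else (),
    )
    write_rrf(
        paths["semgroups"],
        [
            (gid, gname, tui, TUI_NAMES.get(tui, ""))
            for gid, (gname, tuis) in sorted(SEMANTIC_GROUPS.items())
            for tui in tuis
        ],
    )
    write_curation(
        paths["curation"],
        CurationTable(rows=[CurationRow(*row) for row in CURATION_ROWS]),
    )
    _write_reference_citations(paths["reference_citations"], spec)
    return paths


def _write_reference_citations(path: Path, spec: FixtureSpec) -> None:
    lines = []
    if spec.include_reference_tables:
        for pmid, year, expo, _etuis, diso, _dtuis in COVERED_CITATION_EXAMPLES:
            lines.append(f"{pmid}\t{year}\t{expo}\tadverse effects")
            lines.append(f"{pmid}\t{year}\t{diso}\t")
            lines.append(f"{pmid}\t{year}\tHumans\t")
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# Synthetic sectioned notes
# ---------------------------------------------------------------------------


def make_synthetic_notes(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate sectioned notes with planted concept mentions.

    Writes one ``notes/<doc_id>.txt`` per note plus three ground-truth
    tables: ``annotations.tsv`` (the machine-annotation table, generic TSV
    dialect), ``sections.tsv`` (name and offsets of every section) and
    ``plants.tsv`` (per planted mention: section at plant time and whether
    it came from the exposome vocabulary).
    """
    out_dir = Path(out_dir)
    notes_dir = out_dir / "notes"
    notes_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed + 1)

    ann_lines = ["doc_id\tstart\tend\tsurface\tcui\ttuis"]
    sec_lines = ["doc_id\tname\theader_start\tbody_start\tend"]
    plant_lines = ["doc_id\tstart\tend\tterm\tcui\tsection\tis_exposome"]

    for i in range(spec.n_notes):
        doc_id = f"note{i:04d}"
        n_headers = rng.randint(5, min(20, len(SECTION_NAMES)))
        headers = rng.sample(SECTION_NAMES, n_headers)
        mention_budget = max(1, round(rng.gauss(spec.mentions_per_note, 4)))

        pieces: list[str] = []
        offset = 0
        plants: list[tuple[int, int, str, str, tuple[str, ...], str, bool]] = []
        sections: list[tuple[str, int, int, int]] = []  # name, header_start, body_start, end(later)

        def emit(text: str) -> None:
            nonlocal offset
            pieces.append(text)
            offset += len(text)

        def emit_sentence(section_name: str) -> None:
            nonlocal mention_budget
            n_tokens = rng.randint(5, 14)
            tokens = [rng.choice(_FILLER_WORDS) for _ in range(n_tokens)]
            plant = None
            if mention_budget > 0 and rng.random() < 0.5:
                is_expo = rng.random() < spec.exposome_rate
                vocab = EXPOSOME_VOCABULARY if is_expo else BACKGROUND_VOCABULARY
                term, cui, tuis = rng.choice(vocab)
                slot = rng.randint(0, n_tokens - 1)
                plant = (slot, term, cui, tuis, is_expo)
                mention_budget -= 1
            start_of_sentence = offset
            for j, token in enumerate(tokens):
                if plant is not None and j == plant[0]:
                    slot, term, cui, tuis, is_expo = plant
                    plants.append(
                        (offset, offset + len(term), term, cui, tuis, section_name, is_expo)
                    )
                    emit(term)
                else:
                    emit(token)
                emit(" " if j < n_tokens - 1 else ".\n")

        # preamble
        for _ in range(rng.randint(1, 2)):
            emit_sentence("PREAMBLE")
        for name in headers:
            header_start = offset
            emit(f"{name}:")
            body_start = offset
            emit("\n")
            for _ in range(rng.randint(1, 4)):
                emit_sentence(name)
            sections.append((name, header_start, body_start, -1))

        text = "".join(pieces)
        (notes_dir / f"{doc_id}.txt").write_text(text, encoding="utf-8")

        # section truth, mirroring the detector's contract
        first_header = sections[0][1] if sections else len(text)
        sec_lines.append(f"{doc_id}\tPREAMBLE\t0\t0\t{first_header}")
        for k, (name, header_start, body_start, _) in enumerate(sections):
            end = sections[k + 1][1] if k + 1 < len(sections) else len(text)
            sec_lines.append(f"{doc_id}\t{name}\t{header_start}\t{body_start}\t{end}")

        for start, end, term, cui, tuis, section_name, is_expo in plants:
            ann_lines.append(
                f"{doc_id}\t{start}\t{end}\t{term}\t{cui}\t{'|'.join(sorted(tuis))}"
            )
            plant_lines.append(
                f"{doc_id}\t{start}\t{end}\t{term}\t{cui}\t{section_name}\t{int(is_expo)}"
            )

    paths = {
        "notes_dir": notes_dir,
        "annotations": out_dir / "annotations.tsv",
        "sections": out_dir / "sections.tsv",
        "plants": out_dir / "plants.tsv",
    }
    paths["annotations"].write_text("\n".join(ann_lines) + "\n", encoding="utf-8")
    paths["sections"].write_text("\n".join(sec_lines) + "\n", encoding="utf-8")
    paths["plants"].write_text("\n".join(plant_lines) + "\n", encoding="utf-8")
    return paths


# ---------------------------------------------------------------------------
# Synthetic citation corpora
# ---------------------------------------------------------------------------


def _descriptor_pools(
    kept_pairs: Iterable[ExpoDisoPair],
) -> tuple[dict[str, list[str]], dict[str, list[str]], list[tuple[str, str]]]:
    by_tui: dict[str, list[str]] = {}
    for descriptor, _cui, tuis in MESH_DESCRIPTORS:
        for tui in tuis:
            by_tui.setdefault(tui, []).append(descriptor)
    expo_pool = {
        tui: sorted(by_tui.get(tui, [])) for tui in {p.expo for p in kept_pairs}
    }
    diso_pool = {
        tui: sorted(by_tui.get(tui, [])) for tui in {p.diso for p in kept_pairs}
    }
    usable = sorted(
        {
            (p.expo, p.diso)
            for p in kept_pairs
            if expo_pool.get(p.expo) and diso_pool.get(p.diso)
        }
    )
    return expo_pool, diso_pool, usable


def make_synthetic_citations(
    spec: FixtureSpec,
    kept_pairs: Iterable[ExpoDisoPair],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Generate a citation corpus with a planted coverage rate.

    With probability ``planted_coverage_rate`` a citation receives an
    exposure heading (descriptor of an exposure-slot type, qualifier
    "adverse effects") plus a disease heading completing a kept pair;
    otherwise one of three deliberately broken variants: the qualifier
    missing, the disease heading missing, or the qualifier attached to the
    disease descriptor instead.  A per-PMID truth label is written next to
    the corpus.
    """
    kept_pairs = list(kept_pairs)
    expo_pool, diso_pool, usable = _descriptor_pools(kept_pairs)
    if spec.planted_coverage_rate > 0 and not usable:
        raise ValueError(
            "no kept pair has descriptors for both slots; cannot plant coverage"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed + 2)

    cit_lines: list[str] = []
    truth_lines = ["pmid\tyear\tcovered"]
    y0, y1 = spec.year_range
    for i in range(spec.n_citations):
        pmid = str(90000000 + i)
        year = rng.randint(y0, y1)
        covered = rng.random() < spec.planted_coverage_rate
        expo_tui, diso_tui = rng.choice(usable)
        expo_desc = rng.choice(expo_pool[expo_tui])
        diso_desc = rng.choice(diso_pool[diso_tui])
        if covered:
            cit_lines.append(f"{pmid}\t{year}\t{expo_desc}\tadverse effects")
            cit_lines.append(f"{pmid}\t{year}\t{diso_desc}\t")
        else:
            mode = rng.randint(0, 2)
            if mode == 0:  # qualifier missing from the exposure heading
                cit_lines.append(f"{pmid}\t{year}\t{expo_desc}\t")
                cit_lines.append(f"{pmid}\t{year}\t{diso_desc}\t")
            elif mode == 1:  # no disease heading at all
                cit_lines.append(f"{pmid}\t{year}\t{expo_desc}\tadverse effects")
            else:  # qualifier attached to the disease descriptor instead
                cit_lines.append(f"{pmid}\t{year}\t{diso_desc}\tadverse effects")
        if rng.random() < 0.5:
            cit_lines.append(f"{pmid}\t{year}\tHumans\t")
        truth_lines.append(f"{pmid}\t{year}\t{int(covered)}")

    paths = {
        "citations": out_dir / "citations.tsv",
        "truth": out_dir / "citation_truth.tsv",
    }
    paths["citations"].write_text(
        "\n".join(cit_lines) + ("\n" if cit_lines else ""), encoding="utf-8"
    )
    paths["truth"].write_text("\n".join(truth_lines) + "\n", encoding="utf-8")
    return paths


def note_vocabulary() -> dict[str, tuple[str, tuple[str, ...]]]:
    """Term → (cui, tuis) mapping over the full note vocabulary."""
    return {
        term: (cui, tuis)
        for term, cui, tuis in EXPOSOME_VOCABULARY + BACKGROUND_VOCABULARY
    }
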