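# expotype

Semantic modeling of the **exposome** — the totality of nongenetic exposures
(drugs, procedures, devices, behaviors, pathogens) a patient encounters —
built on UMLS-style ontology inputs, with tooling to evaluate the model
against MeSH-indexed literature and to filter concept annotations of
clinical notes down to exposome content.

It is written for biomedical informaticians doing "expotyping": identifying
exposure information in electronic health records the way phenotyping
identifies disease information.

## What it computes

**1. An exposure→disorder type subnetwork.** Starting from the disorder
(DISO) semantic group of a Semantic-Network-style type system (minus T050
*Experimental Model of Disease*), an event template asks *what nongenetic
factors could contribute to a disorder?* and matches four relations over the
fully-inherited type-level relation table:

```
DISO  is result_of       EXPO
DISO  is associated_with EXPO
EXPO  causes             DISO
EXPO  complicates        DISO
```

Every match is a candidate (EXPO type, relation, DISO type) pair; a curation
table of keep/drop decisions — data, not code — yields the kept subnetwork,
exportable as TSV, DOT and GraphML (nodes colored by semantic group).

**2. Disorders of microbial etiology.** Concepts typed T004 *Fungus*, T005
*Virus* or T007 *Bacterium* that stand in a `causative_agent_of` relation to
a disorder-group concept yield (disease, microbe) pairs: a mention of the
disease implies a past pathogen exposure.

**3. Literature coverage.** For a MeSH-indexed citation, a heading counts as
an *exposure* if its descriptor maps (case-insensitive exact synonym match)
to an exposure-slot semantic type **and** carries the subheading
"adverse effects" (or a child: "toxicity", "poisoning"); it counts as a
*disease* if a type fills a disorder slot. The citation is covered when some
heading pair instantiates a kept (EXPO, DISO) type pair. Per-year trends
summarize covered PMIDs, distinct descriptor pairs, percent covered and mean
pairs per PMID.

**4. Clinical-note annotation filtering.** Machine concept annotations
(generic TSV or MetaMap MMI) are kept iff they carry an exposure semantic
type or name a microbe-caused disorder; notes are segmented at uppercase
`HEADER:` lines; distributions over sections and semantic types are ranked;
curated terms transfer to an independent corpus by case-insensitive
word-boundary exact match.

Because real UMLS releases, PubMed snapshots and clinical corpora are
licensed or access-restricted, the package ships a fixture generator that
writes a miniature, self-consistent release embedding the published example
relations plus adversarial distractors, synthetic sectioned notes with
planted mentions, and citation corpora with a planted coverage rate — all
byte-deterministic under a seed.

## Worked example

```python
import tempfile, pathlib
import expotype as x

root = pathlib.Path(tempfile.mkdtemp())
spec = x.FixtureSpec(seed=1)
paths = x.make_umls_fixture(spec, root / "umls")

triples = x.read_type_relations(paths["srstre2"])
groups = x.read_semantic_groups(paths["semgroups"])
template = x.ExposureEventTemplate(diso_types=x.diso_types(groups))
outcome = x.apply_curation(
    x.match_exposure_template(triples, template),
    x.read_curation(paths["curation"]),
    default="drop",
)
print(len(outcome.kept), sorted(x.exposure_types(outcome.kept)))

microbial = x.extract_microbial_disorders(
    x.read_mrrel(paths["mrrel"]), x.read_mrsty(paths["mrsty"]),
    x.read_mrconso(paths["mrconso"]), x.diso_types(groups),
)
print(sorted(m.disease_name for m in microbial)[:3], len(microbial))

index = x.DescriptorIndex(
    x.read_mrconso(paths["mrconso"]), x.read_mrsty(paths["mrsty"]),
    source_filter="MSH",
)
verdicts = x.corpus_coverage(
    x.read_citations(paths["reference_citations"]), outcome.kept, index
)
print(sum(v.covered for _, v in verdicts), "/", len(verdicts), "covered")
```

prints

```
11 ['T055', 'T058', 'T060', 'T061', 'T074', 'T109', 'T121', 'T122']
['Botulism', 'Endotoxemia', 'Miscarriage due to Leptospira'] 8
8 / 8 covered
```

— 11 curated exposure→disorder type pairs over 8 distinct exposure types
(drugs, chemicals, procedures, devices, materials, behaviors); all 8
embedded causative-agent relations recovered despite 30 adversarial
distractor rows; and every embedded exposure-disease citation judged
covered by the subnetwork.

The same pipeline is available from the shell:

```
expotype make-fixtures --seed 1 --out fx --profile corpus
expotype derive-network --srstre2 fx/umls/SRSTRE2 --semgroups fx/umls/SemGroups.txt \
    --curation fx/umls/curation.tsv --out net
expotype extract-microbial --mrrel fx/umls/MRREL.RRF --mrsty fx/umls/MRSTY.RRF \
    --mrconso fx/umls/MRCONSO.RRF --semgroups fx/umls/SemGroups.txt --out micro
expotype coverage --citations fx/citations/citations.tsv --pairs net/kept_pairs.tsv \
    --mrconso fx/umls/MRCONSO.RRF --mrsty fx/umls/MRSTY.RRF --out-prefix cov/run
```

Every command writes a `manifest.json` with the resolved configuration and
SHA-256 checksums of its inputs.

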