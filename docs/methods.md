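# Methods

## The model

The package treats an exposure event as a typed relation between an
exposure-capable entity and a negative health outcome. It operates at two
levels of a UMLS-style terminology:

* **type level** — semantic types (TUIs) linked by fully-inherited
  Semantic-Network relations. The disorder slot of the event template is
  the DISO semantic group with T050 *Experimental Model of Disease* removed
  (an artificial setting, not a patient exposure outcome). Four relations
  participate, each with a fixed orientation: `result_of` and
  `associated_with` take the disorder as relation subject, `causes` and
  `complicates` take the exposure as subject. Matching is purely syntactic;
  semantic adequacy is delegated to a curation table, because a type can
  satisfy the template without being a sensible exposure (the canonical
  counterexample: *Congenital Abnormality associated_with Organism
  Function* — organism function is not an exposure, and the shipped
  curation table drops it).
* **concept level** — CUIs linked by source-vocabulary relations. Microbial
  exposure is inferred from `causative_agent_of` rows whose agent is typed
  fungus/virus/bacterium (T004/T005/T007) and whose outcome carries a
  disorder-group type. A disease concept so linked is read as "was exposed
  to the causative microbe".

Assumptions worth stating: exposure events always manifest as a disorder
(the template is anchored on the DISO slot, so purely beneficial or neutral
exposures are invisible); type-level pairs are an upper bound on meaning
(curation is required); the causative-agent relation in the source
vocabulary is trusted as-is, with no transitive closure over microbe
taxonomies.

## Parameters and defaults

| parameter | default | why |
|---|---|---|
| template relations | the four listed, fixed orientations | the printed event template; configurable as data for other templates |
| disorder group / exclusion | `DISO` minus `T050` | see above |
| uncurated-candidate default | `drop` (strict) | keep-only-verified stance; `keep` gives the exploratory mode |
| microbe types | `{T004, T005, T007}` | the most common microbial exposures |
| MRREL orientation | agent = `CUI2` | NLM reads a row as "CUI2 has RELA to CUI1"; `--agent-column` flips it for data written the other way |
| exposure qualifiers | `{adverse effects, toxicity, poisoning}` | the subheading plus its children; a closed set, so no live MeSH-tree lookup is ever needed |
| descriptor matching | exact, case-insensitive, MeSH-source-restricted | determinism over recall; stemming or fuzzy matching would make coverage verdicts irreproducible |
| MRCONSO filters | language `ENG`, suppress flag `N` | the usual NLM defaults; both are arguments |
| section header pattern | `^[A-Z][A-Z0-9 /-]+:` at line start | "uppercase phrase followed by a colon", made concrete; configurable regex |
| annotation offsets | 0-based, half-open, raw text | unambiguous round-tripping with standoff tools (brat export included) |
| term transfer | word-boundary, case-insensitive, longest-match-first | "exact match" without substring artifacts ("art" in "heart") |

The qualifier requirement is deliberately per-heading: the subheading must
be attached to the exposure descriptor itself, not merely occur elsewhere
in the record. At coverage time only (EXPO TUI, DISO TUI) membership in the
kept-pair set matters; the relation label is ignored.

Two open representational choices are resolved by computing both variants:
the per-year mean of covered pairs per PMID is reported both over all PMIDs
(`mean_pairs_per_pmid`) and over covered PMIDs only; semantic-type
distributions count an annotation once per TUI it carries (section
distributions count it once), and both keys are exposed.

## The synthetic data

Real releases and corpora being licensed or access-restricted, the fixture
generator emulates their *decision structure*, not their scale or language:

* **miniature release** — embeds the eight published causative-agent
  example relations and the published exposure/disease MeSH descriptor
  examples with their types, then surrounds them with ~30 adversarial
  distractors placed at each filter's decision boundary: non-microbe agents
  with disorder outcomes, microbe agents with non-disorder outcomes,
  correct concept pairs on the wrong relation label, outcomes typed only
  T050, suppressed and non-English synonym rows. CUIs of the form
  `C09xxxxx`/`C2xxxxx`/`C3xxxxx` are synthetic.
* **notes** — lowercase filler sentences (mean length ~9.5 tokens) under
  5–20 uppercase section headers drawn from the published section names,
  with concept mentions planted at recorded offsets. A planted mention is
  exposome-qualifying with probability 0.22, emulating the observed
  clinical condition that roughly 78% of machine annotations are
  non-exposome; ~24 mentions per note keeps the corpus desk-sized. Filler
  vocabulary is disjoint from the mention vocabulary, so transfer matching
  has exact generator truth.
* **citations** — each synthetic citation is covered with probability 0.9
  (the observed literature-coverage regime); uncovered citations are
  *broken at the boundary* — qualifier missing, disease heading missing, or
  the qualifier attached to the disease descriptor — rather than random, so
  the verdict logic is tested where it can fail. Truth labels are written
  per PMID.

Everything is byte-deterministic under the spec seed.

What passing tests therefore show: the derivation, filtering and coverage
logic is exact against independent oracles and planted truth. What they do
not show: behaviour on real clinical language (misspellings, negation,
MetaMap errors), real MeSH indexing practice, or the published corpus-scale
counts (454 type pairs, 5667 microbial disorders, ~90% literature coverage,
~78% filtered annotations at full scale) — those depend on the licensed
release and restricted corpora and are context, not test targets; the
synthetic corpora reproduce the *rates* by construction, not by discovery.

## Numerical and procedural choices

* RRF parsing is strict by default (a malformed row aborts, naming the
  line); a permissive skip-and-log mode exists for exploratory use.
* Distribution tables break count ties lexicographically so output is
  stable across runs and platforms.
* Pair identity excludes curation status, so curation relabels without
  changing set membership; status transitions other than
  candidate→kept/dropped raise.
* A disorder concept with several disorder types emits one
  microbial-etiology record per type; a microbe with several microbe types
  reports the alphabetically first (deterministic tie-break).
* Conflicting duplicate curation rows are a validation error, not
  last-wins.
* Section spans store both the header start and the body start; assignment
  uses header-inclusive regions, which tile the document, so every
  annotation gets exactly one section.
* DOT output is serialized directly (node identifiers are TUIs, so no
  quoting edge cases); GraphML goes through networkx.
* Statistical checks on planted rates use binomial confidence intervals;
  the per-year family of checks uses a Bonferroni-adjusted interval.

## Known limitations

* Concept recognition itself is out of scope: MetaMap (or any annotator)
  output is consumed, never produced.
* No negation/temporality handling and no annotation attributes (dosage,
  duration, frequency); the `status` field exists so human curation can be
  recorded, but curation judgments are data supplied by the user.
* Descriptor mapping has no recall mechanism beyond exact synonymy; a
  descriptor absent from the name table silently contributes nothing.
* The curation table shipped with the fixtures covers only the pairs the
  fixtures generate; a full curated table drops in without code change.
* Behavioral-dysfunction exposures typed T048 (e.g. substance-abuse
  concepts) are missed by design unless curation admits T048 into an
  exposure slot — a known blind spot of the type system this model
  inherits.

## Problem sizes

Default study conditions used by the test suite and the acceptance script:
100 random semantic networks (≤50 types, ≤500 triples) for the template
oracle; 1000 synthetic citations at planted rate 0.9; 50 synthetic notes
(~24 mentions each) for the annotation pipeline; the miniature release with
30 distractor relations. These sizes were chosen as the smallest at which
the binomial checks are meaningful and every boundary case occurs.
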