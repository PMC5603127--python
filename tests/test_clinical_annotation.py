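"""Section detection, exposome filtering and distribution summaries."""

import csv
import random

import pytest

import expotype as x
from expotype.clinical_annotation import PREAMBLE, write_annotations_tsv, write_brat_ann


class TestParseAnnotations:
    def test_generic_tsv_row(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("doc1\t10\t19\tcaptopril\tC0900031\tT109|T121\n")
        (ann,) = x.parse_annotations(path)
        assert ann.tuis == {"T109", "T121"}
        assert ann.status == "machine"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("")
        assert x.parse_annotations(path) == []

    def test_offset_validation_names_document(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("doc1\t0\t50\tterm\tC0000001\tT047\n")
        doc = x.ClinicalDocument(doc_id="doc1", text="short text")
        with pytest.raises(ValueError, match="doc1"):
            x.parse_annotations(path, documents=[doc])

    def test_matches_naive_line_parser_on_generated_rows(self, tmp_path):
        rng = random.Random(8)
        rows = []
        for i in range(500):
            start = rng.randint(0, 400)
            rows.append(
                (
                    f"doc{rng.randint(0, 9)}",
                    start,
                    start + rng.randint(1, 20),
                    f"term{i}",
                    f"C{rng.randint(1, 999):07d}",
                    "|".join(sorted(rng.sample(["T047", "T121", "T060"], rng.randint(1, 3)))),
                )
            )
        path = tmp_path / "ann.tsv"
        path.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
        parsed = x.parse_annotations(path)
        assert len(parsed) == 500
        for row, ann in zip(rows, parsed):
            assert (ann.doc_id, ann.start, ann.end, ann.surface, ann.cui) == row[:5]
            assert ann.tuis == set(row[5].split("|"))

    def test_round_trip_through_writer(self, note_corpus, tmp_path):
        _, _, annotations = note_corpus
        path = tmp_path / "out.tsv"
        write_annotations_tsv(path, annotations)
        assert x.parse_annotations(path) == annotations

    def test_mmi_dialect(self, tmp_path):
        path = tmp_path / "out.mmi"
        path.write_text(
            'doc1|MMI|5.18|Haloperidol|C0900007|[orch,phsu]|["haloperidol"-tx-1-"haloperidol"-noun-0]'
            "|TX|117/11|\n"
            "doc1|AA|ignored line\n"
        )
        (ann,) = x.parse_annotations(path, dialect="metamap_mmi")
        assert (ann.start, ann.end) == (117, 128)
        assert ann.tuis == {"T109", "T121"}
        assert ann.surface == "haloperidol"


class TestSections:
    def test_uppercase_header_starts_section(self):
        doc = x.ClinicalDocument(
            doc_id="d", text="intro line.\nSOCIAL HISTORY:\nsmokes daily.\n"
        )
        spans = x.detect_sections(doc)
        assert [s.name for s in spans] == [PREAMBLE, "SOCIAL HISTORY"]
        social = spans[1]
        assert doc.text[social.header_start : social.start] == "SOCIAL HISTORY:"
        assert social.end == len(doc.text)

    def test_document_without_headers_is_one_default_section(self):
        doc = x.ClinicalDocument(doc_id="d", text="no headers here at all.")
        (span,) = x.detect_sections(doc)
        assert span.name == PREAMBLE and (span.start, span.end) == (0, len(doc.text))

    def test_lowercase_and_inline_colons_do_not_split(self):
        doc = x.ClinicalDocument(
            doc_id="d",
            text="Plan: follow up.\nnoted ALLERGIES: penicillin inline\nALLERGIES:\nnone.\n",
        )
        spans = x.detect_sections(doc)
        # "Plan" is mixed case and the inline "ALLERGIES:" is mid-line
        assert [s.name for s in spans] == [PREAMBLE, "ALLERGIES"]

    def test_generated_notes_recovered_exactly(self, note_corpus):
        """Detector output equals generator ground truth on every note."""
        paths, docs, _ = note_corpus
        with open(paths["sections"]) as handle:
            truth = [
                (
                    row["doc_id"],
                    row["name"],
                    int(row["header_start"]),
                    int(row["body_start"]),
                    int(row["end"]),
                )
                for row in csv.DictReader(handle, delimiter="\t")
            ]
        detected = [
            (doc.doc_id, s.name, s.header_start, s.start, s.end)
            for doc in docs
            for s in x.detect_sections(doc)
        ]
        assert detected == truth

    def test_spans_tile_the_document(self, note_corpus):
        _, docs, _ = note_corpus
        for doc in docs:
            spans = x.detect_sections(doc)
            regions = [(s.header_start, s.end) for s in spans]
            assert regions[0][0] == 0 and regions[-1][1] == len(doc.text)
            for (_, prev_end), (nxt_start, _) in zip(regions, regions[1:]):
                assert prev_end == nxt_start


class TestAssignSections:
    def test_annotation_lands_in_containing_section(self):
        doc = x.ClinicalDocument(
            doc_id="d", text="x\nHOSPITAL COURSE:\ngiven haloperidol daily.\n"
        )
        sections = x.detect_sections(doc)
        start = doc.text.index("haloperidol")
        ann = x.ConceptAnnotation("d", start, start + 11, "haloperidol", "C0900007")
        (assigned,) = x.assign_sections([ann], sections)
        assert assigned.section == "HOSPITAL COURSE"

    def test_empty_annotation_list(self, note_corpus):
        _, docs, _ = note_corpus
        assert x.assign_sections([], x.detect_sections(docs[0])) == []

    def test_random_offsets_match_interval_scan_oracle(self, note_corpus):
        rng = random.Random(12)
        _, docs, _ = note_corpus
        for doc in docs[:5]:
            sections = x.detect_sections(doc)
            anns = [
                x.ConceptAnnotation(doc.doc_id, p, p + 1, doc.text[p], "C0000001")
                for p in rng.sample(range(len(doc.text) - 1), 40)
            ]
            assigned = x.assign_sections(anns, sections)
            for ann, got in zip(anns, assigned):
                expected = [
                    s.name for s in sections if s.header_start <= ann.start < s.end
                ]
                assert [got.section] == expected

    def test_planted_mentions_get_their_planted_section(self, note_corpus):
        paths, docs, annotations = note_corpus
        with open(paths["plants"]) as handle:
            truth = {
                (row["doc_id"], int(row["start"])): row["section"]
                for row in csv.DictReader(handle, delimiter="\t")
            }
        by_doc = {doc.doc_id: x.detect_sections(doc) for doc in docs}
        for ann in annotations:
            (assigned,) = x.assign_sections([ann], by_doc[ann.doc_id])
            assert assigned.section == truth[(ann.doc_id, ann.start)]


class TestFilterExposome:
    def test_exposure_type_kept(self):
        ann = x.ConceptAnnotation("d", 0, 4, "drug", "C0900031", frozenset({"T121"}))
        kept, rejected = x.filter_exposome([ann], {"T121"}, set())
        assert len(kept) == 1 and kept[0].status == "kept" and not rejected

    def test_microbial_concept_kept_by_cui(self):
        ann = x.ConceptAnnotation(
            "d", 0, 4, "phn", "C0032768", frozenset({"T047"})
        )
        kept, _ = x.filter_exposome([ann], {"T121"}, {"C0032768"})
        assert len(kept) == 1

    def test_non_microbial_t048_rejected(self):
        # behavior-dysfunction concepts outside the microbial list fall
        # through the filter (the known blind spot)
        ann = x.ConceptAnnotation(
            "d", 0, 11, "cocaine use", "C0900047", frozenset({"T048"})
        )
        kept, rejected = x.filter_exposome([ann], {"T121", "T055"}, {"C0032768"})
        assert not kept and rejected[0].status == "rejected"

    def test_partition_matches_predicate_oracle(self, note_corpus, pipeline):
        _, _, annotations = note_corpus
        kept, rejected = x.filter_exposome(
            annotations, pipeline.expo_tuis, pipeline.microbial_cuis
        )
        assert len(kept) + len(rejected) == len(annotations)
        for ann in kept:
            assert ann.tuis & pipeline.expo_tuis or ann.cui in pipeline.microbial_cuis
        for ann in rejected:
            assert not (ann.tuis & pipeline.expo_tuis) and ann.cui not in pipeline.microbial_cuis
        # order preserved within each part
        spans = lambda anns: [(a.doc_id, a.start) for a in anns]  # noqa: E731
        assert spans(kept) == [
            (a.doc_id, a.start)
            for a in annotations
            if a.tuis & pipeline.expo_tuis or a.cui in pipeline.microbial_cuis
        ]


class TestDistribution:
    def test_counts_and_ordering(self):
        anns = [
            x.ConceptAnnotation("d", i, i + 1, "t", "C0000001", section=s)
            for i, s in enumerate(
                ["HOSPITAL COURSE"] * 3 + ["SOCIAL HISTORY"] * 2 + ["ALLERGIES"] * 2
            )
        ]
        table = x.distribution(anns, key="section")
        assert list(table["section"]) == ["HOSPITAL COURSE", "ALLERGIES", "SOCIAL HISTORY"]
        assert list(table["count"]) == [3, 2, 2]
        assert table["count"].sum() == len(anns)

    def test_semantic_type_mode_counts_per_tui(self):
        anns = [
            x.ConceptAnnotation("d", 0, 1, "t", "C0000001", frozenset({"T109", "T121"})),
            x.ConceptAnnotation("d", 2, 3, "t", "C0000002", frozenset({"T121"})),
        ]
        table = x.distribution(anns, key="semantic_type").set_index("semantic_type")
        assert table.loc["T121", "count"] == 2
        assert table.loc["T109", "count"] == 1
        assert table["count"].sum() == sum(len(a.tuis) for a in anns)

    def test_single_annotation(self):
        (row,) = x.distribution(
            [x.ConceptAnnotation("d", 0, 1, "t", "C0000001", section="A")]
        ).itertuples(index=False)
        assert row == ("A", 1)

    def test_matches_tally_oracle_on_generated_corpus(self, note_corpus):
        paths, docs, annotations = note_corpus
        by_doc = {doc.doc_id: x.detect_sections(doc) for doc in docs}
        sectioned = [
            a
            for ann in annotations
            for a in x.assign_sections([ann], by_doc[ann.doc_id])
        ]
        table = x.distribution(sectioned, key="section").set_index("section")
        tally = {}
        with open(paths["plants"]) as handle:
            for row in csv.DictReader(handle, delimiter="\t"):
                tally[row["section"]] = tally.get(row["section"], 0) + 1
        assert dict(table["count"]) == tally


class TestTransfer:
    def test_case_insensitive_word_boundary_match(self):
        doc = x.ClinicalDocument(
            doc_id="beth1",
            text="SOCIAL HISTORY:\nquit Tobacco Smoking last year; heart ok.\n",
        )
        found = x.transfer_terms({"tobacco smoking": ("C0900020", ("T055",))}, [doc])
        assert len(found) == 1
        (ann,) = found
        assert ann.surface == "Tobacco Smoking" and ann.cui == "C0900020"
        (assigned,) = x.assign_sections([ann], x.detect_sections(doc))
        assert assigned.section == "SOCIAL HISTORY"

    def test_no_substring_artifacts(self):
        doc = x.ClinicalDocument(doc_id="d", text="the heart is fine")
        assert x.transfer_terms(["art"], [doc]) == []

    def test_longest_match_wins(self):
        doc = x.ClinicalDocument(doc_id="d", text="history of cocaine use noted")
        found = x.transfer_terms(
            {"cocaine use": ("C0900047", ("T048",)), "cocaine": ("C0999999", ("T109",))},
            [doc],
        )
        assert [a.surface for a in found] == ["cocaine use"]

    def test_empty_term_set(self, note_corpus):
        _, docs, _ = note_corpus
        assert x.transfer_terms({}, docs) == []

    def test_recovers_exactly_the_planted_occurrences(self, note_corpus):
        _, docs, annotations = note_corpus
        found = x.transfer_terms(x.note_vocabulary(), docs)
        assert {(a.doc_id, a.start, a.end, a.cui) for a in found} == {
            (a.doc_id, a.start, a.end, a.cui) for a in annotations
        }


class TestFilterReduction:
    def test_headline_arithmetic(self):
        assert x.filter_reduction(100, 22) == pytest.approx(78.0)
        assert x.filter_reduction(5, 5) == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            x.filter_reduction(0, 0)
        with pytest.raises(ValueError):
            x.filter_reduction(10, 11)

    def test_random_counts_match_formula(self):
        rng = random.Random(6)
        for _ in range(50):
            machine = rng.randint(1, 500)
            kept = rng.randint(0, machine)
            assert x.filter_reduction(machine, kept) == pytest.approx(
                100.0 * (machine - kept) / machine
            )

    def test_corpus_mean_is_unweighted(self):
        per_doc, mean = x.corpus_filter_reduction(
            {"a": (100, 50), "b": (10, 0), "c": (0, 0)}
        )
        assert per_doc["a"] == pytest.approx(50.0)
        assert per_doc["b"] == pytest.approx(100.0)
        assert per_doc["c"] is None
        assert mean == pytest.approx(75.0)


def test_brat_export_entity_lines(tmp_path):
    anns = [
        x.ConceptAnnotation("d", 0, 4, "drug", "C0900031", frozenset({"T121"}), status="kept")
    ]
    path = tmp_path / "d.ann"
    write_brat_ann(path, anns)
    assert path.read_text() == "T1\tExposome 0 4\tdrug\n"


def test_annotation_span_invariants():
    with pytest.raises(ValueError):
        x.ConceptAnnotation("d", 5, 5, "x", "C0000001")
    with pytest.raises(ValueError):
        x.ClinicalDocument(doc_id="d", text="ab", sentence_spans=((0, 5),))
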