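import pytest

import expotype as x


@pytest.fixture(scope="session")
def fixture_spec():
    return x.FixtureSpec(seed=7, n_notes=10, n_citations=200)


@pytest.fixture(scope="session")
def umls_paths(fixture_spec, tmp_path_factory):
    return x.make_umls_fixture(fixture_spec, tmp_path_factory.mktemp("umls"))


class Pipeline:
    """The derivation pipeline run once over the miniature release."""

    def __init__(self, paths):
        self.paths = paths
        self.triples = x.read_type_relations(paths["srstre2"])
        self.groups = x.read_semantic_groups(paths["semgroups"])
        self.diso = x.diso_types(self.groups)
        self.template = x.ExposureEventTemplate(diso_types=self.diso)
        self.candidates = x.match_exposure_template(self.triples, self.template)
        self.curation = x.read_curation(paths["curation"])
        self.outcome = x.apply_curation(self.candidates, self.curation, default="drop")
        self.kept = self.outcome.kept
        self.expo_tuis = x.exposure_types(self.kept)
        self.names = x.read_mrconso(paths["mrconso"])
        self.assignments = x.read_mrsty(paths["mrsty"])
        self.relations = x.read_mrrel(paths["mrrel"])
        self.microbial = x.extract_microbial_disorders(
            self.relations, self.assignments, self.names, self.diso
        )
        self.microbial_cuis = {m.disease_cui for m in self.microbial}
        self.index = x.DescriptorIndex(self.names, self.assignments, source_filter="MSH")


@pytest.fixture(scope="session")
def pipeline(umls_paths):
    return Pipeline(umls_paths)


@pytest.fixture(scope="session")
def note_corpus(fixture_spec, tmp_path_factory):
    paths = x.make_synthetic_notes(fixture_spec, tmp_path_factory.mktemp("corpus"))
    docs = x.read_corpus(paths["notes_dir"])
    annotations = x.parse_annotations(paths["annotations"], documents=docs)
    return paths, docs, annotations
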