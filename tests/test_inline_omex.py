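import pytest

from omexsim import fixtures
from omexsim.archive import (FORMAT_SBML, FORMAT_SEDML, Archive, ArchiveEntry,
                             pack, unpack)
from omexsim.errors import ParseError
from omexsim.inline_omex import (OmexDocument, archive_to_document,
                                 document_to_archive, parse_document,
                                 render_document)

SIMPLE = """\
model decay
  species S = 10
  J0: S => ; k1*S
  k1 = 0.5
end

m1 = model decay
sim1 = simulate uniform(0, 2, 10)
t1 = run sim1 on m1
report time, S
"""


def test_split_model_and_global_scope():
    doc = parse_document(SIMPLE)
    kinds = [(s.kind, s.archive_path) for s in doc.sections]
    assert kinds == [("model", "model1.xml"), ("simulation", "experiment1.xml")]


def test_empty_document():
    assert parse_document("").sections == []
    assert render_document(OmexDocument()) == ""


def test_antimony_header_sets_path():
    doc = parse_document("%antimony models/a.xml\nmodel m\n  S = 1\nend\n")
    assert doc.sections[0].archive_path == "models/a.xml"


def test_phrasedml_header_sets_path_and_splits_runs():
    text = ("model m\n  species S = 1\n  J0: S => ; k*S\n  k = 1\nend\n"
            "%phrasedml exp/a.xml\n"
            "m1 = model m\nsim1 = simulate uniform(0, 1, 5)\nt1 = run sim1 on m1\n"
            "%phrasedml exp/b.xml\n"
            "m2 = model m\nsim2 = simulate uniform(0, 2, 5)\nt2 = run sim2 on m2\n")
    doc = parse_document(text)
    assert [(s.kind, s.archive_path) for s in doc.sections] == [
        ("model", "model1.xml"),
        ("simulation", "exp/a.xml"),
        ("simulation", "exp/b.xml")]


def test_header_with_missing_path():
    with pytest.raises(ParseError, match="missing path"):
        parse_document("%antimony\nmodel m\nend\n")


def test_unterminated_model_block():
    with pytest.raises(ParseError, match="unterminated"):
        parse_document("model m\n  S = 1\n")


def test_duplicate_paths_rejected():
    text = ("%antimony a.xml\nmodel m1\nend\n"
            "%antimony a.xml\nmodel m2\nend\n")
    with pytest.raises(Exception, match="duplicate"):
        parse_document(text)


@pytest.mark.parametrize("name", fixtures.FIXTURE_NAMES)
def test_render_parse_identity(name):
    doc = parse_document(fixtures.generate_fixture(name))
    assert parse_document(render_document(doc)) == doc


def test_multi_section_render_emits_headers():
    doc = parse_document(SIMPLE)
    text = render_document(doc)
    assert "%antimony model1.xml" in text
    assert "%phrasedml experiment1.xml" in text


def test_document_to_archive_entries():
    arch = document_to_archive(parse_document(SIMPLE))
    assert [e.format_uri for e in arch.entries] == [FORMAT_SBML, FORMAT_SEDML]
    assert [e.master for e in arch.entries] == [False, True]
    assert [e.location for e in arch.entries] == ["model1.xml", "experiment1.xml"]


def test_empty_document_archive_has_manifest_only():
    data = pack(document_to_archive(OmexDocument()))
    arch = unpack(data)
    assert arch.entries == []


def test_archive_document_semantic_roundtrip():
    from omexsim.model_lang import parse_model
    from omexsim.sim_lang import parse_simulation
    doc = parse_document(SIMPLE)
    doc2 = archive_to_document(document_to_archive(doc))
    m1 = parse_model(doc.model_sections()[0].text)
    m2 = parse_model(doc2.model_sections()[0].text)
    assert m1 == m2
    s1 = parse_simulation(doc.simulation_sections()[0].text, {"decay"})
    s2 = parse_simulation(doc2.simulation_sections()[0].text, {"decay"})
    assert (len(s1.tasks), len(s1.simulations), len(s1.outputs)) == \
        (len(s2.tasks), len(s2.simulations), len(s2.outputs))
    assert [m.source for m in s2.model_refs] == ["decay"]
    assert doc2.model_sections()[0].archive_path == "model1.xml"


def test_passthrough_entry_preserved_on_repack():
    doc = parse_document(SIMPLE)
    arch = document_to_archive(doc)
    arch.entries.append(ArchiveEntry("expected.csv", "text/csv", b"time,S\n0,10\n"))
    doc2 = archive_to_document(arch)
    assert [e.location for e in doc2.passthrough] == ["expected.csv"]
    arch2 = document_to_archive(doc2)
    entry = arch2.get("expected.csv")
    assert entry is not None and entry.content == b"time,S\n0,10\n"


def test_counts_and_sbo_preserved_through_archive_loop():
    from omexsim.model_lang import parse_model
    doc = parse_document(fixtures.generate_fixture("sbo_demo"))
    doc2 = archive_to_document(document_to_archive(doc))
    m1 = parse_model(doc.model_sections()[0].text)
    m2 = parse_model(doc2.model_sections()[0].text)
    assert len(m1.species) == len(m2.species)
    assert len(m1.parameters) == len(m2.parameters)
    assert len(m1.reactions) == len(m2.reactions)
    assert dict(m1.parameters) == dict(m2.parameters)
    assert sorted((a.element_id, a.sbo_term) for a in m1.sbo_annotations) == \
        sorted((a.element_id, a.sbo_term) for a in m2.sbo_annotations)
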