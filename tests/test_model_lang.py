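import numpy as np
import pytest

from omexsim import fixtures
from omexsim.errors import ParseError, ValidationError
from omexsim.expr import parse_expr
from omexsim.model_lang import (DEFAULT_COMPARTMENT, parse_model, render_model)


def test_boundary_reactant_reaction():
    doc = parse_model("R23: $UbE => UbE_star; k25*UbE\nk25 = 0.1")
    (r,) = doc.reactions
    assert r.id == "R23"
    assert r.reactants == [("UbE", 1.0)]
    assert r.products == [("UbE_star", 1.0)]
    assert not r.reversible
    assert r.rate_law == parse_expr("k25*UbE")
    assert doc.get_species("UbE").is_boundary
    assert not doc.get_species("UbE_star").is_boundary


def test_reversible_arrow():
    doc = parse_model("A -> B; k1*(A - B)\nk1 = 1")
    assert doc.reactions[0].reversible


def test_assignment_rule_statement():
    with pytest.warns(UserWarning):
        doc = parse_model("StgT := (1 - N*E_1)*Stgc + N*E_1*Stgn")
    assert doc.assignment_rules == [
        ("StgT", parse_expr("(1 - N*E_1)*Stgc + N*E_1*Stgn"))]


def test_sbo_annotation_statement():
    doc = parse_model("compartment C1 = 1\nC1.sboTerm = SBO:0000290")
    (ann,) = doc.sbo_annotations
    assert (ann.element_id, ann.sbo_term) == ("C1", 290)
    assert ann.rendered_term() == "SBO:0000290"


def test_stoichiometric_prefixes():
    doc = parse_model("J0: 2 A => B; k*A*A\nA = 4\nk = 1")
    assert doc.reactions[0].reactants == [("A", 2.0)]


def test_default_compartment_injected():
    doc = parse_model("J0: S => ; k*S\nS = 1\nk = 1")
    assert doc.compartments == [(DEFAULT_COMPARTMENT, 1.0)]
    assert doc.get_species("S").compartment_id == DEFAULT_COMPARTMENT


def test_rate_rule_and_events():
    doc = parse_model(
        "X' = -k*X\nX = 5\nk = 1\nE1: at X < 1: X = 5, k = 2")
    assert doc.rate_rules == [("X", parse_expr("-k*X"))]
    (ev,) = doc.events
    assert ev.id == "E1"
    assert ev.trigger == parse_expr("X < 1")
    assert ev.assignments == [("X", ("num", 5.0)), ("k", ("num", 2.0))]


def test_undeclared_rate_law_identifier_warns_and_creates_parameter():
    with pytest.warns(UserWarning, match="k25"):
        doc = parse_model("R1: A => B; k25*A\nA = 1")
    assert ("k25", 0.0) in doc.parameters


def test_value_before_reaction_still_species():
    # a numeric assignment to an id that later appears in a reaction must
    # set the species initial value, not create a shadowing parameter
    doc = parse_model("S = 10\nJ0: S => ; k*S\nk = 0.5")
    assert doc.get_species("S").initial_value == 10.0
    assert "S" not in doc.parameter_ids()


def test_duplicate_id_rejected():
    with pytest.raises(ValidationError, match="duplicate"):
        parse_model("species A = 1\ncompartment A")


def test_cyclic_assignment_rules_rejected():
    with pytest.raises(ValidationError, match="cyclic"):
        parse_model("a := b + 1\nb := a + 1")


def test_unterminated_block():
    with pytest.raises(ParseError, match="unterminated"):
        parse_model("model m\nspecies A = 1")


def test_comments_stripped():
    doc = parse_model("k = 1  // trailing\n# full line\nS = 2 # other\n"
                      "J0: S => ; k*S")
    assert ("k", 1.0) in doc.parameters
    assert doc.get_species("S").initial_value == 2.0


@pytest.mark.parametrize("name", fixtures.FIXTURE_NAMES)
def test_roundtrip_on_fixture_models(name):
    from omexsim.inline_omex import parse_document
    doc = parse_document(fixtures.generate_fixture(name))
    for section in doc.model_sections():
        m = parse_model(section.text)
        assert parse_model(render_model(m)) == m
        # render is idempotent
        assert render_model(parse_model(render_model(m))) == render_model(m)


@pytest.mark.parametrize("src, expected", [
    # hand-built stoichiometry oracles on tiny networks (state order = species order)
    ("J0: S => ; k*S\nS = 1\nk = 1", [[-1.0]]),
    ("J0: A -> B; k*(A-B)\nA = 1\nk = 1", [[-1.0, 1.0]]),
    ("J0: 2 A => B; k\nJ1: B => 3 C; k\nA = 1\nk = 1",
     [[-2.0, 1.0, 0.0], [0.0, -1.0, 3.0]]),
    ("J0: => X; a\nJ1: X => ; b*X\nX = 0\na = 1\nb = 1",
     [[1.0], [-1.0]]),
    ("J0: E + S => ES; k1*E*S\nJ1: ES => E + P; k2*ES\nE = 1\nk1 = 1\nk2 = 1",
     [[-1.0, -1.0, 1.0, 0.0], [1.0, 0.0, -1.0, 1.0]]),
])
def test_compiled_stoichiometry_matches_hand_oracle(src, expected):
    from omexsim.engine import compile as compile_model
    sys = compile_model(parse_model(src))
    np.testing.assert_array_equal(sys.stoichiometry, np.array(expected))


def test_sbo_annotations_survive_roundtrip():
    src = ("compartment C1 = 1\nC1.sboTerm = SBO:0000290\n"
           "species A in C1 = 1\nA.sboTerm = SBO:0000252\n"
           "J0: A => ; k*A\nJ0.sboTerm = SBO:0000176\nk = 1")
    doc = parse_model(src)
    again = parse_model(render_model(doc))
    assert sorted((a.element_id, a.sbo_term) for a in again.sbo_annotations) == \
        sorted((a.element_id, a.sbo_term) for a in doc.sbo_annotations)
    assert len(again.sbo_annotations) == 3
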