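import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lxml import etree

from omexsim.errors import ParseError
from omexsim.expr import (eval_expr, expr_symbols, expr_to_mathml,
                          map_symbols, mathml_to_expr, parse_expr, render_expr)


@pytest.mark.parametrize("src, env, expected", [
    ("1 + 2*3", {}, 7.0),
    ("2^3^2", {}, 512.0),                       # right-associative power
    ("-2^2", {}, -4.0),                         # unary minus binds looser
    ("(1 - N*E_1)*Stgc + N*E_1*Stgn",
     {"N": 1.95, "E_1": 0.2, "Stgc": 1.0, "Stgn": 2.0}, 1.39),
    ("exp(-1)*10", {}, 10 * math.exp(-1)),
    ("ln(exp(2))", {}, 2.0),
    ("log(100)", {}, 2.0),                      # log is base-10
    ("log10(1000)", {}, 3.0),
    ("pow(2, 10)", {}, 1024.0),
    ("sqrt(16)", {}, 4.0),
    ("abs(-3.5)", {}, 3.5),
    ("piecewise(1, time < 5, 2)", {"time": 3.0}, 1.0),
    ("piecewise(1, time < 5, 2)", {"time": 7.0}, 2.0),
    ("k1*(A - B)", {"k1": 2.0, "A": 5.0, "B": 3.0}, 4.0),
])
def test_eval_matches_closed_form(src, env, expected):
    assert eval_expr(parse_expr(src), env) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("src, env, expected", [
    ("time >= 5", {"time": 5.0}, True),
    ("time >= 5", {"time": 4.0}, False),
    ("A < 2 and B > 1", {"A": 1.0, "B": 2.0}, True),
    ("not A == B", {"A": 1.0, "B": 1.0}, False),
    ("A != B or A > 10", {"A": 1.0, "B": 1.0}, False),
])
def test_boolean_triggers(src, env, expected):
    assert bool(eval_expr(parse_expr(src), env)) is expected


def test_eval_is_vectorized_over_arrays():
    expr = parse_expr("log10(S) + 1")
    out = eval_expr(expr, {"S": np.array([1.0, 10.0, 100.0])})
    np.testing.assert_allclose(out, [1.0, 2.0, 3.0])


@pytest.mark.parametrize("src", [
    "1 + 2*3",
    "2^3^2",
    "-(a + b)/c",
    "(1 - N*E_1)*Stgc + N*E_1*Stgn",
    "piecewise(1, time < 5, 2)",
    "a < b and not c > d",
    "exp(-k*time)*S0",
    "log10(abs(x))",
    "a - (b - c)",
    "a / (b * c)",
])
def test_parse_render_roundtrip(src):
    e = parse_expr(src)
    assert parse_expr(render_expr(e)) == e


@pytest.mark.parametrize("src", [
    "1 +", "foo(1)", "exp(1, 2)", "piecewise(1)", "a ** b", "(a", "1..2",
])
def test_syntax_errors_are_reported(src):
    with pytest.raises(ParseError):
        parse_expr(src)


@pytest.mark.parametrize("src", [
    "k1*S + 2",
    "piecewise(a, time < 5, b)",
    "log10(x) - ln(y)",
    "-x^2 + sqrt(z)",
    "a < b and c >= d or not e == f",
    "pow(x, 2)/abs(y)",
    "time*2",
])
def test_mathml_roundtrip(src):
    e = parse_expr(src)
    ml = expr_to_mathml(e)
    assert mathml_to_expr(ml) == e


def test_mathml_log_base_10_form():
    # log10 must serialize as <log/> with an explicit logbase of 10
    ml = expr_to_mathml(parse_expr("log10(x)"))
    xml = etree.tostring(ml).decode()
    assert "<log/>" in xml and "logbase" in xml and ">10<" in xml
    assert mathml_to_expr(ml) == ("call", "log10", (("sym", "x"),))


def test_time_maps_to_csymbol():
    ml = expr_to_mathml(parse_expr("time + 1"))
    assert b"csymbol" in etree.tostring(ml)
    assert mathml_to_expr(ml) == parse_expr("time + 1")


def test_symbols_and_mapping():
    e = parse_expr("k1*(A - B) + time")
    assert expr_symbols(e) == {"k1", "A", "B", "time"}
    q = map_symbols(e, lambda s: ("sym", f"t1.{s}" if s != "time" else s))
    assert expr_symbols(q) == {"t1.k1", "t1.A", "t1.B", "time"}


_names = st.sampled_from(["a", "b2", "k_1", "time"])


@st.composite
def exprs(draw, depth=0):
    if depth > 3 or draw(st.booleans()):
        if draw(st.booleans()):
            return ("num", float(draw(st.integers(-50, 50))))
        return ("sym", draw(_names))
    op = draw(st.sampled_from(["+", "-", "*", "/", "^", "neg", "call"]))
    if op == "neg":
        inner = draw(exprs(depth=depth + 1))
        # the parser folds unary minus into numeric literals, so a bare
        # ('neg', ('num', x)) node is never produced by a parse
        return inner if inner[0] == "num" else ("neg", inner)
    if op == "call":
        fn = draw(st.sampled_from(["exp", "ln", "log10", "sqrt", "abs"]))
        return ("call", fn, (draw(exprs(depth=depth + 1)),))
    return (op, draw(exprs(depth=depth + 1)), draw(exprs(depth=depth + 1)))


@given(exprs())
@settings(max_examples=200, deadline=None)
def test_roundtrip_property_text_and_mathml(e):
    """Rendered text and MathML both parse back to the identical tree."""
    assert parse_expr(render_expr(e)) == e
    assert mathml_to_expr(expr_to_mathml(e)) == e
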