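"""Math-expression core shared by the model and simulation DSLs.

Expressions are immutable tuple trees:

    ('num', 2.0)                     real literal
    ('bool', True)                   boolean literal
    ('sym', 'k1')                    identifier ('time' is the time symbol)
    ('+' | '-' | '*' | '/' | '^', a, b)
    ('neg', a)                       unary minus
    ('call', name, (arg, ...))       exp, ln, log, log10, pow, sqrt, abs, piecewise
    ('cmp', op, a, b)                op in < <= > >= == !=
    ('and' | 'or', a, b)
    ('not', a)

Tuples compare structurally, which makes round-trip testing trivial.  The
same module renders expressions back to DSL text and to/from the content
MathML subset used by SBML and SED-ML.

`log(x)` is base-10 (an alias of log10); `ln(x)` is natural.  Piecewise
follows SBML semantics: piecewise(v1, c1, v2, c2, ..., [otherwise]).
"""

from __future__ import annotations

import re
import numpy as np
from lxml import etree

from .errors import ParseError

Expr = tuple

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_CSYMBOL_URL = "http://www.sbml.org/sbml/symbols/time"

_FUNCTIONS = {"exp", "ln", "log", "log10", "pow", "sqrt", "abs", "piecewise"}
_FUNC_ARITY = {"exp": 1, "ln": 1, "log": 1, "log10": 1, "pow": 2, "sqrt": 1, "abs": 1}


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<num>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op><=|>=|==|!=|:=|<|>|\+|-|\*|/|\^|\(|\)|,|=|'|\.|\$|:|;|\[|\])
  | (?P<ws>\s+)
  | (?P<bad>.)
    """,
    re.VERBOSE,
)


class Token:
    __slots__ = ("kind", "value", "pos")

    def __init__(self, kind: str, value, pos: int):
        self.kind = kind  # 'num' | 'name' | 'op' | 'end'
        self.value = value
        self.pos = pos

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Token({self.kind!r}, {self.value!r})"


def tokenize(text: str) -> list[Token]:
    toks: list[Token] = []
    for m in _TOKEN_RE.finditer(text):
        kind = m.lastgroup
        if kind == "ws":
            continue
        if kind == "bad":
            raise ParseError(f"unexpected character {m.group()!r}", column=m.start() + 1)
        if kind == "num":
            toks.append(Token("num", float(m.group()), m.start()))
        elif kind == "name":
            toks.append(Token("name", m.group(), m.start()))
        else:
            toks.append(Token("op", m.group(), m.start()))
    toks.append(Token("end", None, len(text)))
    return toks


class TokenStream:
    """Cursor over a token list; shared by the expression and DSL parsers."""

    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.i = 0

    @classmethod
    def of(cls, text: str) -> "TokenStream":
        return cls(tokenize(text))

    def peek(self) -> Token:
        return self.tokens[self.i]

    def next(self) -> Token:
        t = self.tokens[self.i]
        if t.kind != "end":
            self.i += 1
        return t

    def at_end(self) -> bool:
        return self.peek().kind == "end"

    def accept_op(self, *ops: str) -> Token | None:
        t = self.peek()
        if t.kind == "op" and t.value in ops:
            return self.next()
        return None

    def accept_name(self, *names: str) -> Token | None:
        t = self.peek()
        if t.kind == "name" and t.value in names:
            return self.next()
        return None

    def expect_op(self, op: str) -> Token:
        t = self.next()
        if t.kind != "op" or t.value != op:
            raise ParseError(f"expected {op!r}, found {t.value!r}", column=t.pos + 1)
        return t

    def expect_name(self) -> str:
        t = self.next()
        if t.kind != "name":
            raise ParseError(f"expected identifier, found {t.value!r}", column=t.pos + 1)
        return t.value


# ---------------------------------------------------------------------------
# Recursive-descent expression parser
# ---------------------------------------------------------------------------

def parse_expr(source: str | TokenStream) -> Expr:
    ts = TokenStream.of(source) if isinstance(source, str) else source
    expr = _parse_or(ts)
    if isinstance(source, str) and not ts.at_end():
        t = ts.peek()
        raise ParseError(f"trailing input at {t.value!r}", column=t.pos + 1)
    return expr


def _parse_or(ts: TokenStream) -> Expr:
    left = _parse_and(ts)
    while ts.accept_name("or"):
        left = ("or", left, _parse_and(ts))
    return left


def _parse_and(ts: TokenStream) -> Expr:
    left = _parse_not(ts)
    while ts.accept_name("and"):
        left = ("and", left, _parse_not(ts))
    return left


def _parse_not(ts: TokenStream) -> Expr:
    if ts.accept_name("not"):
        return ("not", _parse_not(ts))
    return _parse_cmp(ts)


_CMP_OPS = ("<=", ">=", "==", "!=", "<", ">")


def _parse_cmp(ts: TokenStream) -> Expr:
    left = _parse_add(ts)
    t = ts.peek()
    if t.kind == "op" and t.value in _CMP_OPS:
        ts.next()
        return ("cmp", t.value, left, _parse_add(ts))
    return left


def _parse_add(ts: TokenStream) -> Expr:
    left = _parse_mul(ts)
    while True:
        t = ts.accept_op("+", "-")
        if not t:
            return left
        left = (t.value, left, _parse_mul(ts))


def _parse_mul(ts: TokenStream) -> Expr:
    left = _parse_unary(ts)
    while True:
        t = ts.accept_op("*", "/")
        if not t:
            return left
        left = (t.value, left, _parse_unary(ts))


def _parse_unary(ts: TokenStream) -> Expr:
    if ts.accept_op("-"):
        inner = _parse_unary(ts)
        if inner[0] == "num":
            return ("num", -inner[1])
        return ("neg", inner)
    if ts.accept_op("+"):
        return _parse_unary(ts)
    return _parse_power(ts)


def _parse_power(ts: TokenStream) -> Expr:
    base = _parse_atom(ts)
    if ts.accept_op("^"):
        # right-associative; -x^2 parses as -(x^2) via _parse_unary ordering
        return ("^", base, _parse_unary(ts))
    return base


def _parse_atom(ts: TokenStream) -> Expr:
    t = ts.next()
    if t.kind == "num":
        return ("num", t.value)
    if t.kind == "op" and t.value == "(":
        inner = _parse_or(ts)
        ts.expect_op(")")
        return inner
    if t.kind == "name":
        name = t.value
        if name == "true":
            return ("bool", True)
        if name == "false":
            return ("bool", False)
        if ts.peek().kind == "op" and ts.peek().value == "(" and name in _FUNCTIONS:
            ts.next()
            args = []
            if not (ts.peek().kind == "op" and ts.peek().value == ")"):
                args.append(_parse_or(ts))
                while ts.accept_op(","):
                    args.append(_parse_or(ts))
            ts.expect_op(")")
            _check_arity(name, len(args), t.pos)
            if name == "log":
                name = "log10"
            if name == "pow":  # canonical form: pow(a, b) == a^b
                return ("^", args[0], args[1])
            return ("call", name, tuple(args))
        return ("sym", name)
    raise ParseError(f"unexpected token {t.value!r}", column=t.pos + 1)


def _check_arity(name: str, n: int, pos: int) -> None:
    if name == "piecewise":
        if n < 2:
            raise ParseError("piecewise needs at least a value and a condition", column=pos + 1)
        return
    want = _FUNC_ARITY[name]
    if n != want:
        raise ParseError(f"{name} takes {want} argument(s), got {n}", column=pos + 1)


# ---------------------------------------------------------------------------
# Rendering back to DSL text
# ---------------------------------------------------------------------------

_PREC = {"or": 1, "and": 2, "not": 3, "cmp": 4, "+": 5, "-": 5, "*": 6, "/": 6,
         "neg": 7, "^": 8, "atom": 9}


def render_expr(expr: Expr) -> str:
    return _render(expr, 0)


def _render(e: Expr, parent_prec: int) -> str:
    head = e[0]
    if head == "num":
        v = e[1]
        if v == int(v) and abs(v) < 1e16:
            s = repr(int(v))
        else:
            s = repr(v)
        if v < 0:
            return _wrap(s, _PREC["neg"], parent_prec)
        return s
    if head == "bool":
        return "true" if e[1] else "false"
    if head == "sym":
        return e[1]
    if head == "call":
        return f"{e[1]}({', '.join(_render(a, 0) for a in e[2])})"
    if head == "neg":
        return _wrap("-" + _render(e[1], _PREC["neg"]), _PREC["neg"], parent_prec)
    if head == "not":
        return _wrap("not " + _render(e[1], _PREC["not"]), _PREC["not"], parent_prec)
    if head == "cmp":
        s = f"{_render(e[2], _PREC['cmp'] + 1)} {e[1]} {_render(e[3], _PREC['cmp'] + 1)}"
        return _wrap(s, _PREC["cmp"], parent_prec)
    if head in ("and", "or"):
        p = _PREC[head]
        s = f"{_render(e[1], p)} {head} {_render(e[2], p + 1)}"
        return _wrap(s, p, parent_prec)
    if head in ("+", "-", "*", "/", "^"):
        p = _PREC[head]
        if head == "^":  # right-assoc
            s = f"{_render(e[1], p + 1)}^{_render(e[2], p)}"
        else:
            s = f"{_render(e[1], p)} {head} {_render(e[2], p + 1)}"
        return _wrap(s, p, parent_prec)
    raise ValueError(f"bad expression node {head!r}")


def _wrap(s: str, prec: int, parent_prec: int) -> str:
    return f"({s})" if prec < parent_prec else s


# ---------------------------------------------------------------------------
# Evaluation (numpy-vectorized: scalars and arrays both work)
# ---------------------------------------------------------------------------

def eval_expr(expr: Expr, env: dict):
    head = expr[0]
    if head == "num":
        return expr[1]
    if head == "bool":
        return expr[1]
    if head == "sym":
        try:
            return env[expr[1]]
        except KeyError:
            raise KeyError(f"unbound identifier {expr[1]!r} in expression") from None
    if head == "+":
        return eval_expr(expr[1], env) + eval_expr(expr[2], env)
    if head == "-":
        return eval_expr(expr[1], env) - eval_expr(expr[2], env)
    if head == "*":
        return eval_expr(expr[1], env) * eval_expr(expr[2], env)
    if head == "/":
        return eval_expr(expr[1], env) / eval_expr(expr[2], env)
    if head == "^":
        return eval_expr(expr[1], env) ** eval_expr(expr[2], env)
    if head == "neg":
        return -eval_expr(expr[1], env)
    if head == "cmp":
        a, b = eval_expr(expr[2], env), eval_expr(expr[3], env)
        op = expr[1]
        if op == "<":
            return a < b
        if op == "<=":
            return a <= b
        if op == ">":
            return a > b
        if op == ">=":
            return a >= b
        if op == "==":
            return a == b
        return a != b
    if head == "and":
        return np.logical_and(eval_expr(expr[1], env), eval_expr(expr[2], env))
    if head == "or":
        return np.logical_or(eval_expr(expr[1], env), eval_expr(expr[2], env))
    if head == "not":
        return np.logical_not(eval_expr(expr[1], env))
    if head == "call":
        name, args = expr[1], expr[2]
        if name == "piecewise":
            vals = [eval_expr(a, env) for a in args]
            # pairs (value, condition) ..., optional trailing otherwise
            if len(vals) % 2 == 1:
                result = vals[-1]
                pairs = vals[:-1]
            else:
                result = np.nan
                pairs = vals
            for v, c in reversed(list(zip(pairs[0::2], pairs[1::2]))):
                result = np.where(c, v, result)
            return result[()] if isinstance(result, np.ndarray) and result.ndim == 0 else result
        a = [eval_expr(x, env) for x in args]
        if name == "exp":
            return np.exp(a[0])
        if name == "ln":
            return np.log(a[0])
        if name == "log10":
            return np.log10(a[0])
        if name == "pow":
            return a[0] ** a[1]
        if name == "sqrt":
            return np.sqrt(a[0])
        if name == "abs":
            return np.abs(a[0])
    raise ValueError(f"bad expression node {head!r}")


def expr_symbols(expr: Expr) -> set[str]:
    out: set[str] = set()
    _collect(expr, out)
    return out


def _collect(e: Expr, out: set[str]) -> None:
    if e[0] == "sym":
        out.add(e[1])
    elif e[0] == "call":
        for a in e[2]:
            _collect(a, out)
    elif e[0] not in ("num", "bool"):
        for a in e[1:]:
            if isinstance(a, tuple):
                _collect(a, out)


def map_symbols(expr: Expr, fn) -> Expr:
    """Rewrite every ('sym', name) node via ``fn(name) -> Expr``."""
    head = expr[0]
    if head == "sym":
        return fn(expr[1])
    if head in ("num", "bool"):
        return expr
    if head == "call":
        return ("call", expr[1], tuple(map_symbols(a, fn) for a in expr[2]))
    if head == "cmp":
        return ("cmp", expr[1], map_symbols(expr[2], fn), map_symbols(expr[3], fn))
    return (head,) + tuple(map_symbols(a, fn) for a in expr[1:])


# ---------------------------------------------------------------------------
# MathML (content markup, SBML/SED-ML subset)
# ---------------------------------------------------------------------------

def _m(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


_APPLY_BINOPS = {"+": "plus", "-": "minus", "*": "times", "/": "divide", "^": "power"}
_APPLY_CMP = {"<": "lt", "<=": "leq", ">": "gt", ">=": "geq", "==": "eq", "!=": "neq"}
_CMP_FROM_ML = {v: k for k, v in _APPLY_CMP.items()}


def expr_to_mathml(expr: Expr, wrap_math: bool = True) -> etree._Element:
    """Convert an expression tree to content MathML.

    With ``wrap_math`` the result is a <math> element ready for embedding in
    SBML kinetic laws or SED-ML data generators.
    """
    node = _to_ml(expr)
    if not wrap_math:
        return node
    math = etree.Element(_m("math"), nsmap={None: MATHML_NS})
    math.append(node)
    return math


def _to_ml(e: Expr) -> etree._Element:
    head = e[0]
    if head == "num":
        cn = etree.Element(_m("cn"))
        v = e[1]
        if v == int(v) and abs(v) < 1e16:
            cn.set("type", "integer")
            cn.text = str(int(v))
        else:
            cn.text = repr(v)
        return cn
    if head == "bool":
        return etree.Element(_m("true" if e[1] else "false"))
    if head == "sym":
        if e[1] == "time":
            cs = etree.Element(_m("csymbol"))
            cs.set("encoding", "text")
            cs.set("definitionURL", TIME_CSYMBOL_URL)
            cs.text = "time"
            return cs
        ci = etree.Element(_m("ci"))
        ci.text = e[1]
        return ci
    if head == "neg":
        return _apply("minus", e[1])
    if head == "not":
        return _apply("not", e[1])
    if head in _APPLY_BINOPS:
        return _apply(_APPLY_BINOPS[head], e[1], e[2])
    if head in ("and", "or"):
        return _apply(head, e[1], e[2])
    if head == "cmp":
        return _apply(_APPLY_CMP[e[1]], e[2], e[3])
    if head == "call":
        name, args = e[1], e[2]
        if name == "piecewise":
            pw = etree.Element(_m("piecewise"))
            vals = list(args)
            tail = None
            if len(vals) % 2 == 1:
                tail = vals.pop()
            for v, c in zip(vals[0::2], vals[1::2]):
                piece = etree.SubElement(pw, _m("piece"))
                piece.append(_to_ml(v))
                piece.append(_to_ml(c))
            if tail is not None:
                other = etree.SubElement(pw, _m("otherwise"))
                other.append(_to_ml(tail))
            return pw
        if name == "log10":
            ap = etree.Element(_m("apply"))
            etree.SubElement(ap, _m("log"))
            lb = etree.SubElement(ap, _m("logbase"))
            cn = etree.SubElement(lb, _m("cn"))
            cn.set("type", "integer")
            cn.text = "10"
            ap.append(_to_ml(args[0]))
            return ap
        if name == "sqrt":
            ap = etree.Element(_m("apply"))
            etree.SubElement(ap, _m("root"))
            deg = etree.SubElement(ap, _m("degree"))
            cn = etree.SubElement(deg, _m("cn"))
            cn.set("type", "integer")
            cn.text = "2"
            ap.append(_to_ml(args[0]))
            return ap
        if name == "pow":
            return _apply("power", args[0], args[1])
        return _apply(name, *args)  # exp, ln, abs
    raise ValueError(f"bad expression node {head!r}")


def _apply(op: str, *args: Expr) -> etree._Element:
    ap = etree.Element(_m("apply"))
    etree.SubElement(ap, _m(op))
    for a in args:
        ap.append(_to_ml(a))
    return ap


def mathml_to_expr(node: etree._Element) -> Expr:
    """Parse the content-MathML subset back into an expression tree."""
    tag = etree.QName(node).localname
    if tag == "math":
        children = _element_children(node)
        if len(children) != 1:
            raise ParseError("<math> must contain exactly one expression")
        return mathml_to_expr(children[0])
    if tag == "cn":
        return ("num", float(node.text.strip()))
    if tag == "ci":
        return ("sym", node.text.strip())
    if tag == "csymbol":
        if node.get("definitionURL", "").endswith("/time"):
            return ("sym", "time")
        return ("sym", node.text.strip())
    if tag == "true":
        return ("bool", True)
    if tag == "false":
        return ("bool", False)
    if tag == "piecewise":
        args: list[Expr] = []
        tail: Expr | None = None
        for child in _element_children(node):
            ctag = etree.QName(child).localname
            sub = _element_children(child)
            if ctag == "piece":
                args.append(mathml_to_expr(sub[0]))
                args.append(mathml_to_expr(sub[1]))
            elif ctag == "otherwise":
                tail = mathml_to_expr(sub[0])
        if tail is not None:
            args.append(tail)
        return ("call", "piecewise", tuple(args))
    if tag != "apply":
        raise ParseError(f"unsupported MathML element <{tag}>")

    children = _element_children(node)
    op = etree.QName(children[0]).localname
    operands = children[1:]

    if op == "minus" and len(operands) == 1:
        inner = mathml_to_expr(operands[0])
        if inner[0] == "num":
            return ("num", -inner[1])
        return ("neg", inner)
    if op in ("plus", "times", "minus", "divide", "power"):
        sym = {v: k for k, v in _APPLY_BINOPS.items()}[op]
        exprs = [mathml_to_expr(o) for o in operands]
        out = exprs[0]
        for nxt in exprs[1:]:  # n-ary plus/times fold left
            out = (sym, out, nxt)
        return out
    if op in _CMP_FROM_ML:
        return ("cmp", _CMP_FROM_ML[op], mathml_to_expr(operands[0]), mathml_to_expr(operands[1]))
    if op in ("and", "or"):
        exprs = [mathml_to_expr(o) for o in operands]
        out = exprs[0]
        for nxt in exprs[1:]:
            out = (op, out, nxt)
        return out
    if op == "not":
        return ("not", mathml_to_expr(operands[0]))
    if op == "log":
        # <log/> with optional <logbase>; bare log means base 10 in this subset
        base = 10.0
        rest = []
        for o in operands:
            if etree.QName(o).localname == "logbase":
                base = float(_element_children(o)[0].text)
            else:
                rest.append(o)
        arg = mathml_to_expr(rest[0])
        if base == 10.0:
            return ("call", "log10", (arg,))
        return ("/", ("call", "ln", (arg,)), ("call", "ln", (("num", base),)))
    if op == "root":
        rest = [o for o in operands if etree.QName(o).localname != "degree"]
        return ("call", "sqrt", (mathml_to_expr(rest[0]),))
    if op in ("exp", "ln", "abs"):
        return ("call", op, (mathml_to_expr(operands[0]),))
    raise ParseError(f"unsupported MathML operator <{op}>")


def _element_children(node: etree._Element) -> list[etree._Element]:
    return [c for c in node if isinstance(c.tag, str)]
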