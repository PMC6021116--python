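"""Parser and serializer for the human-readable reaction-network DSL.

The language is an Antimony-style subset.  A model is a sequence of
line-oriented statements, optionally wrapped in ``model <id> ... end``:

    compartment C1 = 1
    species A in C1 = 10, $B in C1 = 0
    R23: $UbE => UbE_star; k25*UbE      # reaction (=> irreversible, -> reversible)
    k25 = 0.1                           # parameter (or species initial) value
    StgT := (1 - N*E_1)*Stgc + N*E_1*Stgn   # assignment rule
    X' = k*X                            # rate rule
    E1: at S < 2: S = 10                # event (fires on false->true transition)
    C1.sboTerm = SBO:0000290            # SBO annotation

A ``$`` prefix marks a boundary species (fixed by the environment, excluded
from the ODE state).  Stoichiometric coefficients are integer prefixes
(``2 A => B``).  Comments run from ``//`` or ``#`` to end of line.
Identifiers used only inside rate laws are implicitly created as parameters
with value 0 (a warning is emitted).  If no compartment is declared, a
``default_compartment`` of size 1 is injected.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .errors import ParseError, ValidationError
from .expr import Expr, TokenStream, expr_symbols, parse_expr, render_expr

DEFAULT_COMPARTMENT = "default_compartment"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Species:
    id: str
    compartment_id: str
    initial_value: float = 0.0
    is_boundary: bool = False


@dataclass
class Reaction:
    id: str
    reactants: list[tuple[str, float]]
    products: list[tuple[str, float]]
    reversible: bool
    rate_law: Expr


@dataclass
class Event:
    id: str
    trigger: Expr
    assignments: list[tuple[str, Expr]]


@dataclass
class SboAnnotation:
    element_id: str
    sbo_term: int

    def rendered_term(self) -> str:
        return f"SBO:{self.sbo_term:07d}"


@dataclass
class ModelDoc:
    id: str = "m"
    compartments: list[tuple[str, float]] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    parameters: list[tuple[str, float]] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    assignment_rules: list[tuple[str, Expr]] = field(default_factory=list)
    rate_rules: list[tuple[str, Expr]] = field(default_factory=list)
    initial_assignments: list[tuple[str, Expr]] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    sbo_annotations: list[SboAnnotation] = field(default_factory=list)

    # -- convenience lookups ------------------------------------------------
    def species_ids(self) -> set[str]:
        return {s.id for s in self.species}

    def parameter_ids(self) -> set[str]:
        return {p for p, _ in self.parameters}

    def compartment_ids(self) -> set[str]:
        return {c for c, _ in self.compartments}

    def all_ids(self) -> set[str]:
        ids = self.species_ids() | self.parameter_ids() | self.compartment_ids()
        ids |= {r.id for r in self.reactions}
        ids |= {e.id for e in self.events}
        return ids

    def get_species(self, sid: str) -> Species | None:
        for s in self.species:
            if s.id == sid:
                return s
        return None

    def validate(self) -> None:
        seen: set[str] = set()
        for cls_ids in (
            [c for c, _ in self.compartments],
            [s.id for s in self.species],
            [p for p, _ in self.parameters],
            [r.id for r in self.reactions],
            [e.id for e in self.events],
        ):
            for i in cls_ids:
                if i in seen:
                    raise ValidationError(f"duplicate id {i!r} in model {self.id!r}")
                seen.add(i)
        known = self.species_ids() | self.parameter_ids() | self.compartment_ids()
        for target, _ in self.assignment_rules + self.rate_rules + self.initial_assignments:
            if target not in known:
                raise ValidationError(f"rule target {target!r} is not declared")
        for s in self.species:
            if s.is_boundary and any(t == s.id for t, _ in self.rate_rules):
                raise ValidationError(f"boundary species {s.id!r} cannot be a rate-rule target")
        for ev in self.events:
            for target, _ in ev.assignments:
                if target not in known:
                    raise ValidationError(f"event target {target!r} is not declared")
        for ann in self.sbo_annotations:
            if ann.element_id not in self.all_ids():
                raise ValidationError(f"SBO annotation targets unknown id {ann.element_id!r}")
        _check_acyclic(self.assignment_rules)


def _check_acyclic(rules: list[tuple[str, Expr]]) -> list[str]:
    """Topologically sort assignment-rule targets; raise on a cycle."""
    targets = {t for t, _ in rules}
    deps = {t: expr_symbols(e) & targets for t, e in rules}
    order: list[str] = []
    mark: dict[str, int] = {}

    def visit(t: str) -> None:
        state = mark.get(t, 0)
        if state == 1:
            raise ValidationError(f"cyclic assignment rules involving {t!r}")
        if state == 2:
            return
        mark[t] = 1
        for d in deps[t]:
            visit(d)
        mark[t] = 2
        order.append(t)

    for t in deps:
        visit(t)
    return order


def assignment_order(doc: ModelDoc) -> list[tuple[str, Expr]]:
    """Assignment rules sorted so each target only depends on earlier ones."""
    order = _check_acyclic(doc.assignment_rules)
    by_target = dict(doc.assignment_rules)
    return [(t, by_target[t]) for t in order]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_SBO_RE = re.compile(r"^\s*([A-Za-z_]\w*)\.sboTerm\s*=\s*SBO:(\d{1,7})\s*;?\s*$")
_MODEL_RE = re.compile(r"^\s*model\s+\*?([A-Za-z_]\w*|\"[^\"]+\")\s*$")
_END_RE = re.compile(r"^\s*end\s*$")


def strip_comments(text: str) -> str:
    out = []
    for line in text.splitlines():
        for marker in ("//", "#"):
            idx = line.find(marker)
            if idx >= 0:
                line = line[:idx]
        out.append(line)
    return "\n".join(out)


def parse_model(text: str, model_id: str | None = None) -> ModelDoc:
    """Parse DSL source (a bare body or a full ``model ... end`` block)."""
    lines = strip_comments(text).splitlines()

    # Unwrap a model...end block if present.
    body: list[tuple[int, str]] = []
    doc_id = model_id or "m"
    in_block = False
    saw_block = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        m = _MODEL_RE.match(line)
        if m and not in_block:
            in_block = saw_block = True
            doc_id = m.group(1).strip('"')
            continue
        if _END_RE.match(line) and in_block:
            in_block = False
            continue
        body.append((lineno, line))
    if in_block:
        raise ParseError(f"unterminated model block {doc_id!r}")
    if saw_block and model_id is not None:
        doc_id = model_id

    doc = ModelDoc(id=doc_id)
    declared_species: dict[str, Species] = {}
    declared_params: dict[str, float] = {}
    default_needed = False

    # Pass 1: explicit declarations and species mentioned in reactions, so
    # later `id = value` statements can be classified correctly.
    boundary_ids: set[str] = set()
    reaction_species: list[str] = []
    for lineno, line in body:
        if line.startswith("species "):
            continue  # handled in pass 2 in order
        if "=>" in line or ("->" in line):
            for sid, bound in _scan_reaction_species(line, lineno):
                if sid not in reaction_species:
                    reaction_species.append(sid)
                if bound:
                    boundary_ids.add(sid)

    # Pass 2: statement classification, in document order.
    for lineno, line in body:
        try:
            _parse_statement(doc, line, declared_species, declared_params, boundary_ids,
                             reaction_species)
        except ParseError as exc:
            raise ParseError(str(exc.args[0]).split(" (line")[0], line=lineno) from None

    # Auto-declare species that only appear inside reactions.
    for sid in reaction_species:
        if sid not in declared_species:
            sp = Species(sid, "", 0.0, sid in boundary_ids)
            declared_species[sid] = sp
            doc.species.append(sp)

    # Default compartment injection.
    if not doc.compartments:
        default_needed = any(True for _ in doc.species)
        if default_needed or doc.species == []:
            doc.compartments.append((DEFAULT_COMPARTMENT, 1.0))
    default_comp = doc.compartments[0][0]
    for sp in doc.species:
        if not sp.compartment_id:
            sp.compartment_id = default_comp

    # Implicit parameters: identifiers used in math but never declared.
    known = doc.species_ids() | set(declared_params) | doc.compartment_ids() | {"time"}
    used: set[str] = set()
    for r in doc.reactions:
        used |= expr_symbols(r.rate_law)
    for _, e in doc.assignment_rules + doc.rate_rules + doc.initial_assignments:
        used |= expr_symbols(e)
    for ev in doc.events:
        used |= expr_symbols(ev.trigger)
        for _, e in ev.assignments:
            used |= expr_symbols(e)
    rule_targets = {t for t, _ in doc.assignment_rules + doc.rate_rules}
    for name in sorted(used - known - rule_targets):
        warnings.warn(f"identifier {name!r} used but never declared; "
                      f"created as parameter with value 0", stacklevel=2)
        declared_params[name] = 0.0
        doc.parameters.append((name, 0.0))
    for name in sorted(rule_targets - known):
        declared_params[name] = 0.0
        doc.parameters.append((name, 0.0))

    doc.validate()
    return doc


def _scan_reaction_species(line: str, lineno: int) -> list[tuple[str, bool]]:
    head = line.split(";")[0]
    if ":" in head.split("=>")[0].split("->")[0]:
        head = head.split(":", 1)[1]
    arrow = "=>" if "=>" in head else "->"
    out = []
    for side in head.split(arrow):
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            m = re.match(r"^(?:\d+(?:\.\d+)?\s+)?(\$?)([A-Za-z_]\w*)$", term)
            if not m:
                raise ParseError(f"malformed species term {term!r} in reaction", line=lineno)
            out.append((m.group(2), m.group(1) == "$"))
    return out


def _parse_statement(doc: ModelDoc, line: str, species: dict[str, Species],
                     params: dict[str, float], boundary_ids: set[str],
                     reaction_species: list[str]) -> None:
    m = _SBO_RE.match(line)
    if m:
        doc.sbo_annotations.append(SboAnnotation(m.group(1), int(m.group(2))))
        return

    if line.startswith("compartment "):
        for part in line[len("compartment "):].rstrip(";").split(","):
            part = part.strip()
            if "=" in part:
                cid, val = part.split("=", 1)
                doc.compartments.append((cid.strip(), float(val)))
            else:
                doc.compartments.append((part, 1.0))
        return

    if line.startswith("species "):
        default_comp = doc.compartments[0][0] if doc.compartments else ""
        for part in line[len("species "):].rstrip(";").split(","):
            part = part.strip()
            m = re.match(r"^(\$?)([A-Za-z_]\w*)(?:\s+in\s+([A-Za-z_]\w*))?"
                         r"(?:\s*=\s*([-+0-9.eE]+))?$", part)
            if not m:
                raise ParseError(f"malformed species declaration {part!r}")
            sid = m.group(2)
            sp = Species(
                id=sid,
                compartment_id=m.group(3) or default_comp,
                initial_value=float(m.group(4)) if m.group(4) else 0.0,
                is_boundary=m.group(1) == "$" or sid in boundary_ids,
            )
            species[sid] = sp
            doc.species.append(sp)
        return

    if "=>" in line or "->" in line:
        _parse_reaction(doc, line, species, boundary_ids, reaction_species)
        return

    # event, possibly labeled:  [id:] at <trigger>: a = e, b = e
    ev_m = re.match(r"^(?:([A-Za-z_]\w*)\s*:\s*)?at\s+(.*)$", line)
    if ev_m:
        _parse_event(doc, ev_m.group(1), ev_m.group(2))
        return

    # rate rule:  id' = expr
    m = re.match(r"^([A-Za-z_]\w*)\s*'\s*=\s*(.*?)\s*;?\s*$", line)
    if m:
        doc.rate_rules.append((m.group(1), parse_expr(m.group(2))))
        return

    # assignment rule:  id := expr
    m = re.match(r"^([A-Za-z_]\w*)\s*:=\s*(.*?)\s*;?\s*$", line)
    if m:
        doc.assignment_rules.append((m.group(1), parse_expr(m.group(2))))
        return

    # value assignment / initial assignment:  [$]id = expr
    m = re.match(r"^(\$?)([A-Za-z_]\w*)\s*=\s*(.*?)\s*;?\s*$", line)
    if m:
        is_bound, target, rhs = m.group(1) == "$", m.group(2), m.group(3)
        expr = parse_expr(rhs)
        if expr[0] == "num":
            value = expr[1]
            if target in species:
                species[target].initial_value = value
                if is_bound:
                    species[target].is_boundary = True
            elif target in reaction_species or is_bound:
                sp = Species(target, "", value, is_bound or target in boundary_ids)
                species[target] = sp
                doc.species.append(sp)
            elif any(c == target for c, _ in doc.compartments):
                doc.compartments = [(c, value if c == target else v)
                                    for c, v in doc.compartments]
            elif target in params:
                params[target] = value
                doc.parameters = [(p, value if p == target else v)
                                  for p, v in doc.parameters]
            else:
                params[target] = value
                doc.parameters.append((target, value))
        else:
            if target not in species and target not in params and \
                    target not in reaction_species:
                params[target] = 0.0
                doc.parameters.append((target, 0.0))
            doc.initial_assignments.append((target, expr))
        return

    raise ParseError(f"cannot parse statement {line!r}")


def _parse_reaction(doc: ModelDoc, line: str, species: dict[str, Species],
                    boundary_ids: set[str], reaction_species: list[str]) -> None:
    if ";" not in line:
        raise ParseError(f"reaction missing ';<rate law>': {line!r}")
    head, rate_src = line.split(";", 1)
    rid = None
    arrow_part = head
    pre_arrow = head.split("=>")[0].split("->")[0]
    if ":" in pre_arrow:
        rid, arrow_part = head.split(":", 1)
        rid = rid.strip()
    reversible = "=>" not in arrow_part
    arrow = "->" if reversible else "=>"
    lhs, rhs = arrow_part.split(arrow)
    reactants = _parse_side(lhs)
    products = _parse_side(rhs)
    if rid is None:
        rid = f"_J{len(doc.reactions)}"
    rate = parse_expr(rate_src.strip().rstrip(";").strip())
    doc.reactions.append(Reaction(rid, reactants, products, reversible, rate))


def _parse_side(src: str) -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = []
    for term in src.split("+"):
        term = term.strip()
        if not term:
            continue
        m = re.match(r"^(?:(\d+(?:\.\d+)?)\s+)?\$?([A-Za-z_]\w*)$", term)
        if not m:
            raise ParseError(f"malformed species reference {term!r}")
        stoich = float(m.group(1)) if m.group(1) else 1.0
        out.append((m.group(2), stoich))
    return out


def _parse_event(doc: ModelDoc, eid: str | None, rest: str) -> None:
    ts = TokenStream.of(rest)
    trigger = parse_expr(ts)
    ts.expect_op(":")
    assignments: list[tuple[str, Expr]] = []
    while True:
        target = ts.expect_name()
        ts.expect_op("=")
        assignments.append((target, parse_expr(ts)))
        if not ts.accept_op(","):
            break
    if not ts.at_end():
        t = ts.peek()
        raise ParseError(f"trailing input in event at {t.value!r}")
    if eid is None:
        eid = f"_E{len(doc.events)}"
    doc.events.append(Event(eid, trigger, assignments))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(v)


def render_model(doc: ModelDoc, wrap: bool = True) -> str:
    """Serialize a ModelDoc; ``parse_model(render_model(doc)) == doc``."""
    sbo_by_id: dict[str, list[SboAnnotation]] = {}
    for ann in doc.sbo_annotations:
        sbo_by_id.setdefault(ann.element_id, []).append(ann)

    def sbo_lines(element_id: str) -> list[str]:
        return [f"  {a.element_id}.sboTerm = {a.rendered_term()}"
                for a in sbo_by_id.pop(element_id, [])]

    lines: list[str] = []
    for cid, size in doc.compartments:
        lines.append(f"  compartment {cid} = {_fmt(size)}")
        lines.extend(sbo_lines(cid))
    for sp in doc.species:
        prefix = "$" if sp.is_boundary else ""
        lines.append(f"  species {prefix}{sp.id} in {sp.compartment_id}"
                     f" = {_fmt(sp.initial_value)}")
        lines.extend(sbo_lines(sp.id))
    for r in doc.reactions:
        arrow = "->" if r.reversible else "=>"
        boundary = {s.id for s in doc.species if s.is_boundary}

        def side(refs: list[tuple[str, float]]) -> str:
            terms = []
            for sid, st in refs:
                pre = "$" if sid in boundary else ""
                terms.append((f"{_fmt(st)} " if st != 1 else "") + pre + sid)
            return " + ".join(terms)

        lines.append(f"  {r.id}: {side(r.reactants)} {arrow} {side(r.products)};"
                     f" {render_expr(r.rate_law)}")
        lines.extend(sbo_lines(r.id))
    for pid, value in doc.parameters:
        lines.append(f"  {pid} = {_fmt(value)}")
        lines.extend(sbo_lines(pid))
    for target, e in doc.initial_assignments:
        lines.append(f"  {target} = {render_expr(e)}")
    for target, e in doc.assignment_rules:
        lines.append(f"  {target} := {render_expr(e)}")
    for target, e in doc.rate_rules:
        lines.append(f"  {target}' = {render_expr(e)}")
    for ev in doc.events:
        assigns = ", ".join(f"{t} = {render_expr(e)}" for t, e in ev.assignments)
        lines.append(f"  {ev.id}: at {render_expr(ev.trigger)}: {assigns}")
        lines.extend(sbo_lines(ev.id))
    for anns in sbo_by_id.values():  # annotations on ids rendered nowhere else
        for a in anns:
            lines.append(f"  {a.element_id}.sboTerm = {a.rendered_term()}")

    body = "\n".join(lines)
    if wrap:
        return f"model {doc.id}\n{body}\nend" if body else f"model {doc.id}\nend"
    return "\n".join(ln.strip() for ln in lines)
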