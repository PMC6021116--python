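"""SBML Level 3 Version 1 (core) reader/writer for the supported subset.

Writing always targets L3V1 core.  Reading accepts any L3 document and maps
L2 documents onto the same subset (units and stoichiometryMath are ignored).
Species initialConcentration values are converted to amounts at read time
(amount = concentration x compartment size at t0), so the in-memory model is
always amount-based.

Constructs outside the subset — algebraic rules, event delays, fast
reactions, function definitions, SBML packages — raise
:class:`~omexsim.errors.UnsupportedFeatureError` naming the construct.
"""

from __future__ import annotations

from lxml import etree

from .errors import ParseError, UnsupportedFeatureError
from .expr import MATHML_NS, expr_to_mathml, mathml_to_expr
from .model_lang import (DEFAULT_COMPARTMENT, Event, ModelDoc, Reaction,
                         SboAnnotation, Species)

SBML_L3V1_NS = "http://www.sbml.org/sbml/level3/version1/core"


def _fmt(v: float) -> str:
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(v)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_sbml(doc: ModelDoc) -> str:
    """Serialize a ModelDoc as SBML L3V1 core XML text."""
    doc.validate()
    nsmap = {None: SBML_L3V1_NS}
    sbml = etree.Element(f"{{{SBML_L3V1_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "1")
    model = etree.SubElement(sbml, _t("model"))
    model.set("id", doc.id)

    sbo = {ann.element_id: ann.sbo_term for ann in doc.sbo_annotations}

    def set_sbo(el: etree._Element, eid: str) -> None:
        if eid in sbo:
            el.set("sboTerm", f"SBO:{sbo[eid]:07d}")

    compartments = doc.compartments or [(DEFAULT_COMPARTMENT, 1.0)]
    loc = etree.SubElement(model, _t("listOfCompartments"))
    for cid, size in compartments:
        c = etree.SubElement(loc, _t("compartment"))
        c.set("id", cid)
        c.set("size", _fmt(size))
        c.set("constant", "true")
        set_sbo(c, cid)

    if doc.species:
        los = etree.SubElement(model, _t("listOfSpecies"))
        for sp in doc.species:
            s = etree.SubElement(los, _t("species"))
            s.set("id", sp.id)
            s.set("compartment", sp.compartment_id or compartments[0][0])
            s.set("initialAmount", _fmt(sp.initial_value))
            s.set("hasOnlySubstanceUnits", "true")
            s.set("boundaryCondition", "true" if sp.is_boundary else "false")
            s.set("constant", "false")
            set_sbo(s, sp.id)

    rule_targets = {t for t, _ in doc.assignment_rules + doc.rate_rules}
    if doc.parameters:
        lop = etree.SubElement(model, _t("listOfParameters"))
        for pid, value in doc.parameters:
            p = etree.SubElement(lop, _t("parameter"))
            p.set("id", pid)
            p.set("value", _fmt(value))
            p.set("constant", "false" if pid in rule_targets else "true")
            set_sbo(p, pid)

    if doc.initial_assignments:
        loi = etree.SubElement(model, _t("listOfInitialAssignments"))
        for target, expr in doc.initial_assignments:
            ia = etree.SubElement(loi, _t("initialAssignment"))
            ia.set("symbol", target)
            ia.append(expr_to_mathml(expr))

    if doc.assignment_rules or doc.rate_rules:
        lor = etree.SubElement(model, _t("listOfRules"))
        for target, expr in doc.assignment_rules:
            r = etree.SubElement(lor, _t("assignmentRule"))
            r.set("variable", target)
            r.append(expr_to_mathml(expr))
        for target, expr in doc.rate_rules:
            r = etree.SubElement(lor, _t("rateRule"))
            r.set("variable", target)
            r.append(expr_to_mathml(expr))

    if doc.reactions:
        lorx = etree.SubElement(model, _t("listOfReactions"))
        for rx in doc.reactions:
            r = etree.SubElement(lorx, _t("reaction"))
            r.set("id", rx.id)
            r.set("reversible", "true" if rx.reversible else "false")
            r.set("fast", "false")
            set_sbo(r, rx.id)
            for tag, refs in (("listOfReactants", rx.reactants),
                              ("listOfProducts", rx.products)):
                if refs:
                    lst = etree.SubElement(r, _t(tag))
                    for sid, stoich in refs:
                        ref = etree.SubElement(lst, _t("speciesReference"))
                        ref.set("species", sid)
                        ref.set("stoichiometry", _fmt(stoich))
                        ref.set("constant", "true")
            kl = etree.SubElement(r, _t("kineticLaw"))
            kl.append(expr_to_mathml(rx.rate_law))

    if doc.events:
        loe = etree.SubElement(model, _t("listOfEvents"))
        for ev in doc.events:
            e = etree.SubElement(loe, _t("event"))
            e.set("id", ev.id)
            e.set("useValuesFromTriggerTime", "true")
            set_sbo(e, ev.id)
            tr = etree.SubElement(e, _t("trigger"))
            tr.set("initialValue", "true")
            tr.set("persistent", "true")
            tr.append(expr_to_mathml(ev.trigger))
            loa = etree.SubElement(e, _t("listOfEventAssignments"))
            for target, expr in ev.assignments:
                ea = etree.SubElement(loa, _t("eventAssignment"))
                ea.set("variable", target)
                ea.append(expr_to_mathml(expr))

    return etree.tostring(sbml, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode()


def _t(tag: str) -> str:
    return f"{{{SBML_L3V1_NS}}}{tag}"


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_sbml(xml: str | bytes) -> ModelDoc:
    """Parse SBML XML (L3, or L2 mapped) into a ModelDoc."""
    if isinstance(xml, str):
        xml = xml.encode()
    try:
        root = etree.fromstring(xml)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed SBML XML: {exc}") from None
    ns = etree.QName(root).namespace or ""
    if not ns.startswith("http://www.sbml.org/sbml/level"):
        raise ParseError(f"not an SBML document (namespace {ns!r})")

    def find(el, *path):
        cur = el
        for p in path:
            if cur is None:
                return None
            cur = cur.find(f"{{{ns}}}{p}")
        return cur

    def findall(el, *path):
        cur = el
        for p in path[:-1]:
            if cur is None:
                return []
            cur = cur.find(f"{{{ns}}}{p}")
        if cur is None:
            return []
        return cur.findall(f"{{{ns}}}{path[-1]}")

    model = find(root, "model")
    if model is None:
        raise ParseError("SBML document has no <model>")
    if find(model, "listOfFunctionDefinitions") is not None:
        raise UnsupportedFeatureError("function definitions")

    doc = ModelDoc(id=model.get("id") or "m")

    def grab_sbo(el, eid: str) -> None:
        term = el.get("sboTerm")
        if term:
            doc.sbo_annotations.append(SboAnnotation(eid, int(term.split(":")[-1])))

    comp_size: dict[str, float] = {}
    for c in findall(model, "listOfCompartments", "compartment"):
        size = c.get("size", c.get("volume", "1"))
        cid = c.get("id")
        comp_size[cid] = float(size)
        doc.compartments.append((cid, float(size)))
        grab_sbo(c, cid)
    if not doc.compartments:
        doc.compartments.append((DEFAULT_COMPARTMENT, 1.0))
        comp_size[DEFAULT_COMPARTMENT] = 1.0

    for s in findall(model, "listOfSpecies", "species"):
        sid = s.get("id")
        comp = s.get("compartment") or doc.compartments[0][0]
        if s.get("initialConcentration") is not None:
            value = float(s.get("initialConcentration")) * comp_size.get(comp, 1.0)
        else:
            value = float(s.get("initialAmount", "0") or "0")
        doc.species.append(Species(
            id=sid, compartment_id=comp, initial_value=value,
            is_boundary=s.get("boundaryCondition") == "true"))
        grab_sbo(s, sid)

    for p in findall(model, "listOfParameters", "parameter"):
        pid = p.get("id")
        doc.parameters.append((pid, float(p.get("value", "0") or "0")))
        grab_sbo(p, pid)

    for ia in findall(model, "listOfInitialAssignments", "initialAssignment"):
        math = find(ia, "math") or ia.find(f"{{{MATHML_NS}}}math")
        doc.initial_assignments.append((ia.get("symbol"), mathml_to_expr(math)))

    rules = find(model, "listOfRules")
    if rules is not None:
        for rule in rules:
            if not isinstance(rule.tag, str):
                continue
            tag = etree.QName(rule).localname
            math = rule.find(f"{{{MATHML_NS}}}math")
            if tag == "algebraicRule":
                raise UnsupportedFeatureError("algebraic rule")
            if tag == "assignmentRule":
                doc.assignment_rules.append((rule.get("variable"), mathml_to_expr(math)))
            elif tag == "rateRule":
                doc.rate_rules.append((rule.get("variable"), mathml_to_expr(math)))

    for r in findall(model, "listOfReactions", "reaction"):
        if r.get("fast") == "true":
            raise UnsupportedFeatureError("fast reaction", r.get("id", ""))
        rid = r.get("id") or f"_J{len(doc.reactions)}"
        grab_sbo(r, rid)

        def refs(tag: str) -> list[tuple[str, float]]:
            return [(ref.get("species"), float(ref.get("stoichiometry", "1")))
                    for ref in findall(r, tag, "speciesReference")]

        kl = find(r, "kineticLaw")
        if kl is None:
            raise UnsupportedFeatureError("reaction without kinetic law", rid)
        math = kl.find(f"{{{MATHML_NS}}}math")
        # L2 kineticLaw-local parameters become global (prefixed on clash)
        for lp in (findall(kl, "listOfParameters", "parameter")
                   + findall(kl, "listOfLocalParameters", "localParameter")):
            doc.parameters.append((lp.get("id"), float(lp.get("value", "0") or "0")))
        doc.reactions.append(Reaction(
            rid, refs("listOfReactants"), refs("listOfProducts"),
            r.get("reversible", "true") == "true", mathml_to_expr(math)))

    for e in findall(model, "listOfEvents", "event"):
        eid = e.get("id") or f"_E{len(doc.events)}"
        if find(e, "delay") is not None:
            raise UnsupportedFeatureError("event delay", eid)
        trigger = find(e, "trigger")
        tmath = trigger.find(f"{{{MATHML_NS}}}math")
        assignments = []
        for ea in findall(e, "listOfEventAssignments", "eventAssignment"):
            amath = ea.find(f"{{{MATHML_NS}}}math")
            assignments.append((ea.get("variable"), mathml_to_expr(amath)))
        doc.events.append(Event(eid, mathml_to_expr(tmath), assignments))
        grab_sbo(e, eid)

    doc.validate()
    return doc
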