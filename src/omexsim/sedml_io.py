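"""SED-ML Level 1 reader/writer for the supported experiment subset.

Writes the Level 1 Version 2 namespace; reading also accepts Version 1 and
Version 3 documents.  Algorithm keywords are translated to KiSAO ids through
a mapping table shipped as package data (``data/kisao_map.json``) and
overridable per call.

Supported elements: models with changeAttribute changes, uniformTimeCourse
and steadyState simulations (with algorithm + algorithmParameter children),
tasks, one-level repeatedTask with uniformRange or vectorRange,
dataGenerators over task variables and time, plot2D and report outputs.
functionalRange, computeChange with math, plot3D and dataDescription raise
:class:`~omexsim.errors.UnsupportedFeatureError`.
"""

from __future__ import annotations

import json
import re
from importlib import resources

from lxml import etree

from .errors import ParseError, UnsupportedFeatureError, ValidationError
from .expr import MATHML_NS, expr_to_mathml, map_symbols, mathml_to_expr
from .model_lang import ModelDoc
from .sim_lang import (DataGen, ModelRef, Output, RepeatedTask, Simulation,
                       SimulationSpec, Task)

SEDML_NS_WRITE = "http://sed-ml.org/sed-ml/level1/version2"
SEDML_NS_ACCEPTED = (
    "http://sed-ml.org/sed-ml/level1/version1",
    "http://sed-ml.org/sed-ml/level1/version2",
    "http://sed-ml.org/sed-ml/level1/version3",
    "http://sed-ml.org/sed-ml/level1/version4",
)
SBML_LANGUAGE_URN = "urn:sedml:language:sbml.level-3.version-1"
TIME_SYMBOL_URN = "urn:sedml:symbol:time"


def load_kisao_map() -> dict:
    with resources.files("omexsim.data").joinpath("kisao_map.json").open() as fh:
        return json.load(fh)


_KISAO = load_kisao_map()
_ALG_TO_KISAO = _KISAO["algorithms"]
_KISAO_TO_ALG = {v: k for k, v in _ALG_TO_KISAO.items()}
_PARAM_TO_KISAO = _KISAO["parameters"]
_KISAO_TO_PARAM = {v: k for k, v in _PARAM_TO_KISAO.items()}

STEADYSTATE_KISAO = "KISAO:0000407"  # steady-state root-finding method


def _fmt(v: float) -> str:
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(v)


def _param_target_xpath(pid: str) -> str:
    return f"/sbml:sbml/sbml:model/descendant::*[@id='{pid}']/@value"


def _species_target_xpath(sid: str) -> str:
    return (f"/sbml:sbml/sbml:model/descendant::*[@id='{sid}']"
            f"/@initialConcentration|@initialAmount")


def _target_id(xpath: str) -> str:
    m = re.search(r"@id='([^']+)'", xpath)
    if not m:
        raise ParseError(f"cannot extract element id from XPath target {xpath!r}")
    return m.group(1)


def _var_id(sym: str, used: set[str]) -> str:
    base = re.sub(r"[^A-Za-z0-9_]+", "_", sym) or "v"
    vid, i = base, 1
    while vid in used:
        i += 1
        vid = f"{base}_{i}"
    used.add(vid)
    return vid


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_sedml(spec: SimulationSpec, model_paths: dict[str, str],
                model_docs: dict[str, ModelDoc] | None = None,
                kisao_map: dict | None = None) -> str:
    """Serialize a SimulationSpec as SED-ML L1V2 XML text.

    ``model_paths`` maps model-section ids to archive locations; sources that
    already look like paths are used verbatim.  ``model_docs`` (optional)
    lets the writer distinguish parameter targets from species targets when
    building change XPaths; without it all changes use the parameter form.
    """
    spec.validate()
    alg_map = (kisao_map or _KISAO)["algorithms"]
    par_map = (kisao_map or _KISAO)["parameters"]

    nsmap = {None: SEDML_NS_WRITE}
    root = etree.Element(f"{{{SEDML_NS_WRITE}}}sedML", nsmap=nsmap)
    root.set("level", "1")
    root.set("version", "2")

    def sub(parent, tag):
        return etree.SubElement(parent, f"{{{SEDML_NS_WRITE}}}{tag}")

    def resolve_source(source: str) -> str:
        if source in model_paths:
            return model_paths[source]
        if source.endswith(".xml"):
            return source
        raise ValidationError(f"cannot resolve model source {source!r} to a path")

    def change_xpath(model_ref: ModelRef, target: str) -> str:
        if model_docs:
            mdoc = model_docs.get(model_ref.source) \
                or model_docs.get(resolve_source(model_ref.source))
            if mdoc is not None and mdoc.get_species(target) is not None:
                return _species_target_xpath(target)
        return _param_target_xpath(target)

    lom = sub(root, "listOfModels")
    for m in spec.model_refs:
        el = sub(lom, "model")
        el.set("id", m.id)
        el.set("language", SBML_LANGUAGE_URN)
        el.set("source", resolve_source(m.source))
        if m.changes:
            loc = sub(el, "listOfChanges")
            for target, value in m.changes:
                ch = sub(loc, "changeAttribute")
                ch.set("target", change_xpath(m, target))
                ch.set("newValue", _fmt(value))

    los = sub(root, "listOfSimulations")
    for s in spec.simulations:
        if s.kind == "steady_state":
            el = sub(los, "steadyState")
            el.set("id", s.id)
        else:
            el = sub(los, "uniformTimeCourse")
            el.set("id", s.id)
            el.set("initialTime", _fmt(s.t0))
            el.set("outputStartTime", _fmt(s.t0))
            el.set("outputEndTime", _fmt(s.t_end))
            el.set("numberOfPoints", str(s.n_points))
        alg = sub(el, "algorithm")
        alg.set("kisaoID", STEADYSTATE_KISAO if s.kind == "steady_state"
                else alg_map[s.algorithm])
        params: list[tuple[str, str]] = []
        if s.rtol is not None:
            params.append((par_map["relative_tolerance"], repr(s.rtol)))
        if s.atol is not None:
            params.append((par_map["absolute_tolerance"], repr(s.atol)))
        if s.seed is not None:
            params.append((par_map["seed"], str(s.seed)))
        if s.variable_step_size:
            params.append((par_map["variable_step_size"], "true"))
        if params:
            lap = sub(alg, "listOfAlgorithmParameters")
            for kid, value in params:
                ap = sub(lap, "algorithmParameter")
                ap.set("kisaoID", kid)
                ap.set("value", value)

    lot = sub(root, "listOfTasks")
    for t in spec.tasks:
        el = sub(lot, "task")
        el.set("id", t.id)
        el.set("modelReference", t.model_ref)
        el.set("simulationReference", t.simulation)
    for rt in spec.repeated_tasks:
        el = sub(lot, "repeatedTask")
        el.set("id", rt.id)
        el.set("range", f"{rt.id}_range")
        el.set("resetModel", "true" if rt.reset_model else "false")
        lor = sub(el, "listOfRanges")
        if rt.range_uniform is not None:
            rng = sub(lor, "uniformRange")
            rng.set("id", f"{rt.id}_range")
            lo, hi, n = rt.range_uniform
            rng.set("start", _fmt(lo))
            rng.set("end", _fmt(hi))
            # SED-ML uniformRange counts intervals; n values = n-1 intervals
            rng.set("numberOfPoints", str(n - 1))
            rng.set("type", "linear")
        else:
            rng = sub(lor, "vectorRange")
            rng.set("id", f"{rt.id}_range")
            for v in rt.range_values:
                val = sub(rng, "value")
                val.text = _fmt(v)
        # locate the base task's model for the setValue element
        base = rt.subtask
        model_ref_id = None
        seen = set()
        while model_ref_id is None and base not in seen:
            seen.add(base)
            for t in spec.tasks:
                if t.id == base:
                    model_ref_id = t.model_ref
                    break
            else:
                for r2 in spec.repeated_tasks:
                    if r2.id == base:
                        base = r2.subtask
                        break
        loch = sub(el, "listOfChanges")
        sv = sub(loch, "setValue")
        sv.set("target", _param_target_xpath(rt.range_target))
        sv.set("range", f"{rt.id}_range")
        if model_ref_id:
            sv.set("modelReference", model_ref_id)
        math = etree.SubElement(sv, f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
        ci = etree.SubElement(math, f"{{{MATHML_NS}}}ci")
        ci.text = f"{rt.id}_range"
        lost = sub(el, "listOfSubTasks")
        st = sub(lost, "subTask")
        st.set("order", "1")
        st.set("task", rt.subtask)

    lodg = sub(root, "listOfDataGenerators")
    for g in spec.data_generators:
        el = sub(lodg, "dataGenerator")
        el.set("id", g.id)
        used: set[str] = set()
        sym_to_var: dict[str, str] = {}
        syms = sorted({s for s in _datagen_symbols(g)}, key=str)
        lov = sub(el, "listOfVariables") if syms else None
        for sym in syms:
            vid = _var_id(sym, used)
            sym_to_var[sym] = vid
            var = sub(lov, "variable")
            var.set("id", vid)
            if "." in sym:
                task, name = sym.split(".", 1)
            else:
                task, name = None, sym
            if task:
                var.set("taskReference", task)
            if name == "time":
                var.set("symbol", TIME_SYMBOL_URN)
            else:
                var.set("target", f"/sbml:sbml/sbml:model/descendant::*[@id='{name}']")
        math_expr = map_symbols(g.math, lambda s: ("sym", sym_to_var.get(s, s)))
        el.append(expr_to_mathml(math_expr))

    loo = sub(root, "listOfOutputs")
    for i, o in enumerate(spec.outputs):
        if o.kind == "plot2d":
            el = sub(loo, "plot2D")
            el.set("id", f"output{i + 1}")
            el.set("name", o.title)
            loc = sub(el, "listOfCurves")
            for j, (label, xg, yg) in enumerate(o.curves):
                c = sub(loc, "curve")
                c.set("id", f"output{i + 1}_curve{j + 1}")
                c.set("name", label)
                c.set("logX", "false")
                c.set("logY", "false")
                c.set("xDataReference", xg)
                c.set("yDataReference", yg)
        else:
            el = sub(loo, "report")
            el.set("id", f"output{i + 1}")
            el.set("name", o.title)
            lod = sub(el, "listOfDataSets")
            for j, col in enumerate(o.columns):
                d = sub(lod, "dataSet")
                d.set("id", f"output{i + 1}_col{j + 1}")
                d.set("label", col)
                d.set("dataReference", col)

    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode()


def _datagen_symbols(g: DataGen):
    from .expr import expr_symbols
    return expr_symbols(g.math)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_sedml(xml: str | bytes, kisao_map: dict | None = None) -> SimulationSpec:
    """Parse SED-ML XML into a SimulationSpec (inverse of :func:`write_sedml`)."""
    if isinstance(xml, str):
        xml = xml.encode()
    try:
        root = etree.fromstring(xml)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed SED-ML XML: {exc}") from None
    ns = etree.QName(root).namespace or ""
    if ns not in SEDML_NS_ACCEPTED:
        raise ParseError(f"not a supported SED-ML document (namespace {ns!r})")
    alg_from_kisao = {v: k for k, v in (kisao_map or _KISAO)["algorithms"].items()}
    param_from_kisao = {v: k for k, v in (kisao_map or _KISAO)["parameters"].items()}

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

    if find(root, "listOfDataDescriptions") is not None:
        raise UnsupportedFeatureError("dataDescription")

    spec = SimulationSpec()

    for m in findall(root, "listOfModels", "model"):
        changes = []
        for ch in findall(m, "listOfChanges", "changeAttribute"):
            changes.append((_target_id(ch.get("target")), float(ch.get("newValue"))))
        for ch in findall(m, "listOfChanges", "computeChange"):
            raise UnsupportedFeatureError("computeChange with math")
        spec.model_refs.append(ModelRef(m.get("id"), m.get("source"), changes))

    lsims = find(root, "listOfSimulations")
    if lsims is not None:
        for el in lsims:
            if not isinstance(el.tag, str):
                continue
            tag = etree.QName(el).localname
            if tag == "oneStep":
                raise UnsupportedFeatureError("oneStep simulation")
            sim = Simulation(el.get("id"))
            if tag == "steadyState":
                sim.kind = "steady_state"
            elif tag == "uniformTimeCourse":
                sim.kind = "uniform_timecourse"
                sim.t0 = float(el.get("initialTime", "0"))
                sim.t_end = float(el.get("outputEndTime"))
                sim.n_points = int(el.get("numberOfPoints"))
            else:
                raise UnsupportedFeatureError(f"simulation kind {tag}")
            alg = find(el, "algorithm")
            if alg is not None:
                kid = alg.get("kisaoID", "")
                if kid in alg_from_kisao:
                    sim.algorithm = alg_from_kisao[kid]
                for ap in findall(alg, "listOfAlgorithmParameters", "algorithmParameter"):
                    pname = param_from_kisao.get(ap.get("kisaoID"))
                    value = ap.get("value")
                    if pname == "relative_tolerance":
                        sim.rtol = float(value)
                    elif pname == "absolute_tolerance":
                        sim.atol = float(value)
                    elif pname == "seed":
                        sim.seed = int(value)
                    elif pname == "variable_step_size":
                        sim.variable_step_size = value == "true"
                    elif ap.get("kisaoID") in alg_from_kisao and value == "algorithm":
                        sim.algorithm = alg_from_kisao[ap.get("kisaoID")]
            spec.simulations.append(sim)

    ltasks = find(root, "listOfTasks")
    if ltasks is not None:
        for el in ltasks:
            if not isinstance(el.tag, str):
                continue
            tag = etree.QName(el).localname
            if tag == "task":
                spec.tasks.append(Task(el.get("id"),
                                       model_ref=el.get("modelReference"),
                                       simulation=el.get("simulationReference")))
            elif tag == "repeatedTask":
                if find(el, "listOfRanges", "functionalRange") is not None:
                    raise UnsupportedFeatureError("functionalRange")
                subtasks = findall(el, "listOfSubTasks", "subTask")
                if len(subtasks) != 1:
                    raise UnsupportedFeatureError(
                        "repeatedTask with multiple subTasks")
                sv = find(el, "listOfChanges", "setValue")
                if sv is None:
                    raise UnsupportedFeatureError("repeatedTask without setValue")
                target = _target_id(sv.get("target"))
                rt = RepeatedTask(el.get("id"), subtasks[0].get("task"), target,
                                  reset_model=el.get("resetModel") == "true")
                ur = find(el, "listOfRanges", "uniformRange")
                vr = find(el, "listOfRanges", "vectorRange")
                if ur is not None:
                    rt.range_uniform = (float(ur.get("start")), float(ur.get("end")),
                                        int(ur.get("numberOfPoints")) + 1)
                elif vr is not None:
                    rt.range_values = [float(v.text)
                                       for v in vr.findall(f"{{{ns}}}value")]
                else:
                    raise UnsupportedFeatureError("repeatedTask range kind")
                spec.repeated_tasks.append(rt)

    for el in findall(root, "listOfDataGenerators", "dataGenerator"):
        var_to_sym: dict[str, str] = {}
        for var in findall(el, "listOfVariables", "variable"):
            task = var.get("taskReference")
            if var.get("symbol") == TIME_SYMBOL_URN:
                name = "time"
            elif var.get("target"):
                name = _target_id(var.get("target"))
            else:
                name = var.get("id")
            var_to_sym[var.get("id")] = f"{task}.{name}" if task else name
        for par in findall(el, "listOfParameters", "parameter"):
            var_to_sym[par.get("id")] = par.get("id")
        math = el.find(f"{{{MATHML_NS}}}math")
        expr = mathml_to_expr(math)
        expr = map_symbols(expr, lambda s: ("sym", var_to_sym.get(s, s)))
        spec.data_generators.append(DataGen(el.get("id"), expr))

    louts = find(root, "listOfOutputs")
    if louts is not None:
        for el in louts:
            if not isinstance(el.tag, str):
                continue
            tag = etree.QName(el).localname
            if tag == "plot2D":
                curves = []
                for c in findall(el, "listOfCurves", "curve"):
                    curves.append((c.get("name") or c.get("id"),
                                   c.get("xDataReference"), c.get("yDataReference")))
                spec.outputs.append(Output("plot2d", el.get("name") or el.get("id"),
                                           curves=curves))
            elif tag == "plot3D":
                raise UnsupportedFeatureError("plot3D")
            elif tag == "report":
                cols = [d.get("dataReference")
                        for d in findall(el, "listOfDataSets", "dataSet")]
                spec.outputs.append(Output("report", el.get("name") or el.get("id"),
                                           columns=cols))

    spec.validate()
    return spec
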