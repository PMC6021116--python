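"""Parser and serializer for the simulation-experiment DSL.

A PhraSEDML-style shorthand covering the four experiment-description roles:
model instantiation, simulation settings, tasks, and outputs.

    m1 = model "novak" with k1 = 0.5, k2 = 2
    sim1 = simulate uniform(0, 120, 1000)      # t0, tEnd, intervals (n+1 rows)
    sim2 = simulate steadystate
    sim1.algorithm = gillespie                 # lsoda (default) | cvode | gillespie | rk4
    sim1.variable_step_size = true
    sim1.relative_tolerance = 1e-6
    sim1.absolute_tolerance = 1e-12
    sim1.seed = 1234
    t1 = run sim1 on m1
    t2 = repeat t1 for k1 in uniform(0.1, 1, 5), reset=true
    t3 = repeat t1 for k1 in [0.1, 0.5, 1]
    plot "title" time vs S1, S2
    plot log10(time) vs log10(mRNA)
    report time, S1, t1.S2

Plot/report operands may qualify variables with a task id (``t1.S2``).
Unqualified variables are expanded over every task defined so far, which is
how one plot statement draws curves for several model instantiations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ParseError, ValidationError
from .expr import Expr, expr_symbols, map_symbols, parse_expr, render_expr

ALGORITHMS = ("lsoda", "cvode", "gillespie", "rk4")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ModelRef:
    id: str
    source: str                      # model-section id or archive path
    changes: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class Simulation:
    id: str
    kind: str = "uniform_timecourse"     # or "steady_state"
    t0: float = 0.0
    t_end: float = 10.0
    n_points: int = 100                  # intervals; rows = n_points + 1
    algorithm: str = "lsoda"
    variable_step_size: bool = False
    rtol: float | None = None
    atol: float | None = None
    seed: int | None = None


@dataclass
class Task:
    id: str
    model_ref: str
    simulation: str


@dataclass
class RepeatedTask:
    id: str
    subtask: str
    range_target: str
    range_values: list[float] | None = None          # explicit list
    range_uniform: tuple[float, float, int] | None = None   # (lo, hi, n values)
    reset_model: bool = False

    def values(self) -> list[float]:
        if self.range_values is not None:
            return list(self.range_values)
        lo, hi, n = self.range_uniform
        if n == 1:
            return [lo]
        step = (hi - lo) / (n - 1)
        return [lo + i * step for i in range(n)]


@dataclass
class DataGen:
    id: str
    math: Expr      # symbols are "taskId.varId" (dot form) or "time"


@dataclass
class Output:
    kind: str                     # "plot2d" | "report"
    title: str
    curves: list[tuple[str, str, str]] = field(default_factory=list)  # (label, xGen, yGen)
    columns: list[str] = field(default_factory=list)                  # DataGen ids


@dataclass
class SimulationSpec:
    model_refs: list[ModelRef] = field(default_factory=list)
    simulations: list[Simulation] = field(default_factory=list)
    tasks: list[Task] = field(default_factory=list)
    repeated_tasks: list[RepeatedTask] = field(default_factory=list)
    data_generators: list[DataGen] = field(default_factory=list)
    outputs: list[Output] = field(default_factory=list)

    def task_ids(self) -> list[str]:
        return [t.id for t in self.tasks] + [t.id for t in self.repeated_tasks]

    def get_task(self, tid: str):
        for t in self.tasks + self.repeated_tasks:
            if t.id == tid:
                return t
        return None

    def get_simulation(self, sid: str) -> Simulation | None:
        for s in self.simulations:
            if s.id == sid:
                return s
        return None

    def get_model_ref(self, mid: str) -> ModelRef | None:
        for m in self.model_refs:
            if m.id == mid:
                return m
        return None

    def get_datagen(self, gid: str) -> DataGen | None:
        for g in self.data_generators:
            if g.id == gid:
                return g
        return None

    def validate(self) -> None:
        ids: set[str] = set()
        for group in (self.model_refs, self.simulations, self.tasks,
                      self.repeated_tasks, self.data_generators):
            for item in group:
                if item.id in ids:
                    raise ValidationError(f"duplicate id {item.id!r}")
                ids.add(item.id)
        sims = {s.id for s in self.simulations}
        models = {m.id for m in self.model_refs}
        for t in self.tasks:
            if t.model_ref not in models:
                raise ValidationError(f"task {t.id!r} references unknown model {t.model_ref!r}")
            if t.simulation not in sims:
                raise ValidationError(f"task {t.id!r} references unknown simulation"
                                      f" {t.simulation!r}")
        task_ids = set(self.task_ids())
        for rt in self.repeated_tasks:
            if rt.subtask not in task_ids or rt.subtask == rt.id:
                raise ValidationError(f"repeated task {rt.id!r} has bad subtask"
                                      f" {rt.subtask!r}")
            if not rt.values():
                raise ValidationError(f"repeated task {rt.id!r} has an empty range")
        gens = {g.id for g in self.data_generators}
        for g in self.data_generators:
            for sym in expr_symbols(g.math):
                if sym == "time":
                    continue
                task = sym.split(".", 1)[0]
                if task not in task_ids:
                    raise ValidationError(f"data generator {g.id!r} references unknown"
                                          f" task in {sym!r}")
        for o in self.outputs:
            if o.kind == "plot2d":
                if not o.curves:
                    raise ValidationError("plot with no curves")
                for _, x, y in o.curves:
                    if x not in gens or y not in gens:
                        raise ValidationError(f"plot references undefined data generator")
            else:
                if not o.columns:
                    raise ValidationError("report with no columns")
                for c in o.columns:
                    if c not in gens:
                        raise ValidationError(f"report references undefined data generator")
        for s in self.simulations:
            if s.kind == "uniform_timecourse":
                if s.t_end <= s.t0:
                    raise ValidationError(f"simulation {s.id!r}: t_end must exceed t0")
                if s.n_points < 1:
                    raise ValidationError(f"simulation {s.id!r}: n_points must be >= 1")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_PROPS = {"algorithm", "variable_step_size", "relative_tolerance",
          "absolute_tolerance", "seed"}


def parse_simulation(text: str, known_models: set[str] | None = None) -> SimulationSpec:
    """Parse global-scope experiment statements into a SimulationSpec.

    ``known_models`` is the set of model ids defined elsewhere in the same
    document; when given, ``model "x"`` sources are checked against it.
    """
    from .model_lang import strip_comments

    spec = SimulationSpec()
    plot_count = 0
    for lineno, raw in enumerate(strip_comments(text).splitlines(), start=1):
        line = raw.strip().rstrip(";")
        if not line:
            continue
        try:
            plot_count = _parse_sim_statement(spec, line, known_models, plot_count)
        except ParseError as exc:
            raise ParseError(str(exc.args[0]).split(" (line")[0], line=lineno) from None
    spec.validate()
    return spec


def _parse_sim_statement(spec: SimulationSpec, line: str,
                         known_models: set[str] | None, plot_count: int) -> int:
    if line.startswith("plot") and (line == "plot" or line[4] in " \t\""):
        _parse_plot(spec, line[4:].strip(), f"plot{plot_count + 1}")
        return plot_count + 1
    if line.startswith("report") and (line == "report" or line[6] in " \t\""):
        _parse_report(spec, line[6:].strip())
        return plot_count

    # property statement: simId.prop = value
    m = re.match(r"^([A-Za-z_]\w*)\.([A-Za-z_]\w*)\s*=\s*(.+)$", line)
    if m and m.group(2) in _PROPS:
        _set_property(spec, m.group(1), m.group(2), m.group(3).strip())
        return plot_count

    m = re.match(r"^([A-Za-z_]\w*)\s*=\s*(.+)$", line)
    if not m:
        raise ParseError(f"cannot parse statement {line!r}")
    lhs, rhs = m.group(1), m.group(2).strip()

    if rhs.startswith("model"):
        spec.model_refs.append(_parse_model_ref(lhs, rhs, known_models))
    elif rhs.startswith("simulate"):
        spec.simulations.append(_parse_simulate(lhs, rhs))
    elif rhs.startswith("run "):
        m2 = re.match(r"^run\s+([A-Za-z_]\w*)\s+on\s+([A-Za-z_]\w*)$", rhs)
        if not m2:
            raise ParseError(f"malformed task statement {rhs!r}")
        spec.tasks.append(Task(lhs, model_ref=m2.group(2), simulation=m2.group(1)))
    elif rhs.startswith("repeat "):
        spec.repeated_tasks.append(_parse_repeat(lhs, rhs))
    else:
        raise ParseError(f"cannot parse statement {line!r}")
    return plot_count


def _parse_model_ref(lhs: str, rhs: str, known_models: set[str] | None) -> ModelRef:
    m = re.match(r"^model\s+(\"[^\"]+\"|[A-Za-z_][\w./-]*)\s*(?:with\s+(.*))?$", rhs)
    if not m:
        raise ParseError(f"malformed model statement {rhs!r}")
    source = m.group(1).strip('"')
    if known_models is not None and not source.endswith(".xml") \
            and source not in known_models:
        raise ParseError(f"unknown model id {source!r}")
    changes: list[tuple[str, float]] = []
    if m.group(2):
        for pair in m.group(2).split(","):
            pm = re.match(r"^\s*([A-Za-z_]\w*)\s*=\s*([-+0-9.eE]+)\s*$", pair)
            if not pm:
                raise ParseError(f"malformed with-clause entry {pair.strip()!r}")
            changes.append((pm.group(1), float(pm.group(2))))
    return ModelRef(lhs, source, changes)


def _parse_simulate(lhs: str, rhs: str) -> Simulation:
    body = rhs[len("simulate"):].strip()
    if body in ("steadystate", "steadyState"):
        return Simulation(lhs, kind="steady_state")
    m = re.match(r"^uniform\s*\(\s*([^,]+),\s*([^,]+),\s*(\d+)\s*\)$", body)
    if m:
        return Simulation(lhs, kind="uniform_timecourse", t0=float(m.group(1)),
                          t_end=float(m.group(2)), n_points=int(m.group(3)))
    m = re.match(r"^uniform_stochastic\s*\(\s*([^,]+),\s*([^,]+),\s*(\d+)\s*\)$", body)
    if m:
        return Simulation(lhs, kind="uniform_timecourse", t0=float(m.group(1)),
                          t_end=float(m.group(2)), n_points=int(m.group(3)),
                          algorithm="gillespie")
    raise ParseError(f"malformed simulate statement {rhs!r}")


def _set_property(spec: SimulationSpec, sim_id: str, prop: str, value: str) -> None:
    sim = spec.get_simulation(sim_id)
    if sim is None:
        raise ParseError(f"property set on unknown simulation {sim_id!r}")
    if prop == "algorithm":
        if value not in ALGORITHMS:
            raise ParseError(f"unknown algorithm {value!r} (expected one of {ALGORITHMS})")
        sim.algorithm = value
    elif prop == "variable_step_size":
        if value not in ("true", "false"):
            raise ParseError(f"variable_step_size must be true or false, got {value!r}")
        sim.variable_step_size = value == "true"
    elif prop == "relative_tolerance":
        sim.rtol = float(value)
    elif prop == "absolute_tolerance":
        sim.atol = float(value)
    elif prop == "seed":
        sim.seed = int(value)


def _parse_repeat(lhs: str, rhs: str) -> RepeatedTask:
    m = re.match(r"^repeat\s+([A-Za-z_]\w*)\s+for\s+([A-Za-z_]\w*)\s+in\s+(.*)$", rhs)
    if not m:
        raise ParseError(f"malformed repeat statement {rhs!r}")
    subtask, target, rng = m.group(1), m.group(2), m.group(3).strip()
    reset = False
    rm = re.search(r",\s*reset\s*=\s*(true|false)\s*$", rng)
    if rm:
        reset = rm.group(1) == "true"
        rng = rng[:rm.start()].strip()
    um = re.match(r"^uniform\s*\(\s*([^,]+),\s*([^,]+),\s*(\d+)\s*\)$", rng)
    if um:
        return RepeatedTask(lhs, subtask, target, range_uniform=(
            float(um.group(1)), float(um.group(2)), int(um.group(3))), reset_model=reset)
    lm = re.match(r"^\[([^\]]*)\]$", rng)
    if lm:
        values = [float(v) for v in lm.group(1).split(",") if v.strip()]
        return RepeatedTask(lhs, subtask, target, range_values=values, reset_model=reset)
    raise ParseError(f"malformed range {rng!r}")


# -- plot / report operands -------------------------------------------------

def _split_operands(src: str) -> list[str]:
    """Split on top-level commas (not inside parentheses)."""
    out, depth, cur = [], 0, []
    for ch in src:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            out.append("".join(cur).strip())
            cur = []
        else:
            cur.append(ch)
    tail = "".join(cur).strip()
    if tail:
        out.append(tail)
    return out


_DOTTED_RE = re.compile(r"\b([A-Za-z_]\w*)\s*\.\s*([A-Za-z_]\w*)\b")


def _parse_operand_expr(src: str) -> Expr:
    # rewrite task.var into a single token before parsing
    rewritten = _DOTTED_RE.sub(lambda m: f"{m.group(1)}__DOT__{m.group(2)}", src)
    expr = parse_expr(rewritten)
    return map_symbols(expr, lambda s: ("sym", s.replace("__DOT__", ".")))


def _qualify(expr: Expr, task_id: str) -> Expr:
    def fn(sym: str):
        if "." in sym:
            return ("sym", sym)
        return ("sym", f"{task_id}.{sym}")
    return map_symbols(expr, fn)


def _operand_label(expr: Expr) -> str:
    return render_expr(expr)


def _intern_datagen(spec: SimulationSpec, expr: Expr) -> str:
    """Create (or reuse) a data generator with the given math; return its id."""
    for g in spec.data_generators:
        if g.math == expr:
            return g.id
    base = re.sub(r"[^A-Za-z0-9_]+", "_", render_expr(expr)).strip("_") or "dg"
    gid = base
    i = 1
    existing = {g.id for g in spec.data_generators}
    while gid in existing:
        i += 1
        gid = f"{base}_{i}"
    spec.data_generators.append(DataGen(gid, expr))
    return gid


def _expand_tasks(spec: SimulationSpec, expr: Expr) -> list[tuple[str | None, Expr]]:
    """Expand unqualified operands over every task; qualified ones pass through."""
    syms = expr_symbols(expr)
    unqualified = [s for s in syms if "." not in s]  # includes bare `time`
    if not unqualified:
        tasks = sorted({s.split(".", 1)[0] for s in syms if "." in s})
        return [(tasks[0] if tasks else None, expr)]
    task_ids = spec.task_ids()
    if not task_ids:
        raise ParseError(f"plot/report references {unqualified[0]!r} but no task is defined")
    if unqualified == ["time"]:
        # a pure-time operand is shared; one copy per task keeps the task link
        return [(tid, _qualify(expr, tid)) for tid in task_ids]
    return [(tid, _qualify(expr, tid)) for tid in task_ids]


def _parse_plot(spec: SimulationSpec, src: str, default_title: str) -> None:
    title = default_title
    tm = re.match(r'^"([^"]*)"\s*(.*)$', src)
    if tm:
        title, src = tm.group(1), tm.group(2)
    if not src.strip():
        raise ParseError("plot statement with no operands")
    groups = _split_operands(src)
    curves: list[tuple[str, str, str]] = []
    x_src: str | None = None
    for group in groups:
        if " vs " in f" {group} ":
            parts = re.split(r"\bvs\b", group)
            if len(parts) != 2:
                raise ParseError(f"malformed curve {group!r}")
            x_src, y_src = parts[0].strip(), parts[1].strip()
        else:
            if x_src is None:
                raise ParseError(f"curve {group!r} has no x operand")
            y_src = group.strip()
        x_expr = _parse_operand_expr(x_src)
        y_expr = _parse_operand_expr(y_src)
        y_per_task = _expand_tasks(spec, y_expr)
        for tid, y_q in y_per_task:
            x_q = _qualify(x_expr, tid) if tid else x_expr
            xg = _intern_datagen(spec, x_q)
            yg = _intern_datagen(spec, y_q)
            label = _operand_label(y_q)
            curves.append((label, xg, yg))
    spec.outputs.append(Output(kind="plot2d", title=title, curves=curves))


def _parse_report(spec: SimulationSpec, src: str) -> None:
    title = f"report{sum(1 for o in spec.outputs if o.kind == 'report') + 1}"
    tm = re.match(r'^"([^"]*)"\s*(.*)$', src)
    if tm:
        title, src = tm.group(1), tm.group(2)
    if not src.strip():
        raise ParseError("report statement with no columns")
    columns: list[str] = []
    for operand in _split_operands(src):
        expr = _parse_operand_expr(operand)
        for _, q in _expand_tasks(spec, expr):
            columns.append(_intern_datagen(spec, q))
    spec.outputs.append(Output(kind="report", title=title, columns=columns))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(v)


def render_simulation(spec: SimulationSpec) -> str:
    """Serialize a SimulationSpec; ``parse_simulation(render(spec)) == spec``."""
    lines: list[str] = []
    for m in spec.model_refs:
        src = m.source if re.fullmatch(r"[A-Za-z_]\w*", m.source) else f'"{m.source}"'
        stmt = f"{m.id} = model \"{m.source}\"" if src.startswith('"') \
            else f"{m.id} = model {m.source}"
        if m.changes:
            stmt += " with " + ", ".join(f"{k} = {_fmt(v)}" for k, v in m.changes)
        lines.append(stmt)
    for s in spec.simulations:
        if s.kind == "steady_state":
            lines.append(f"{s.id} = simulate steadystate")
        else:
            lines.append(f"{s.id} = simulate uniform({_fmt(s.t0)}, {_fmt(s.t_end)},"
                         f" {s.n_points})")
        if s.algorithm != "lsoda":
            lines.append(f"{s.id}.algorithm = {s.algorithm}")
        if s.variable_step_size:
            lines.append(f"{s.id}.variable_step_size = true")
        if s.rtol is not None:
            lines.append(f"{s.id}.relative_tolerance = {s.rtol!r}")
        if s.atol is not None:
            lines.append(f"{s.id}.absolute_tolerance = {s.atol!r}")
        if s.seed is not None:
            lines.append(f"{s.id}.seed = {s.seed}")
    for t in spec.tasks:
        lines.append(f"{t.id} = run {t.simulation} on {t.model_ref}")
    for rt in spec.repeated_tasks:
        if rt.range_uniform is not None:
            lo, hi, n = rt.range_uniform
            rng = f"uniform({_fmt(lo)}, {_fmt(hi)}, {n})"
        else:
            rng = "[" + ", ".join(_fmt(v) for v in rt.range_values) + "]"
        stmt = f"{rt.id} = repeat {rt.subtask} for {rt.range_target} in {rng}"
        if rt.reset_model:
            stmt += ", reset=true"
        lines.append(stmt)
    gen_by_id = {g.id: g for g in spec.data_generators}
    for o in spec.outputs:
        if o.kind == "plot2d":
            parts = []
            for _, xg, yg in o.curves:
                xs = render_expr(gen_by_id[xg].math)
                ys = render_expr(gen_by_id[yg].math)
                parts.append(f"{xs} vs {ys}")
            lines.append(f'plot "{o.title}" ' + ", ".join(parts))
        else:
            cols = ", ".join(render_expr(gen_by_id[c].math) for c in o.columns)
            lines.append(f'report "{o.title}" {cols}')
    return "\n".join(lines)
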