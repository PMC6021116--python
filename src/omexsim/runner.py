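"""Experiment execution: run a whole inline OMEX document end to end.

Parses every section, executes each task (and repeated task) in document
order, evaluates data generators, materializes plots and reports as labeled
numeric datasets, and can compare trajectories against expected results with
the maximum-MSE criterion (a trajectory comparison fails when any column's
mean squared error reaches 1e-3).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import engine, model_lang, sim_lang
from .engine import ComparisonResult, SimulationResult
from .errors import EngineError, ValidationError
from .expr import eval_expr, expr_symbols
from .inline_omex import OmexDocument
from .sim_lang import DataGen, RepeatedTask, Simulation, SimulationSpec

MSE_THRESHOLD = 1e-3


@dataclass
class Series:
    label: str
    x: np.ndarray
    y: np.ndarray


@dataclass
class PlotData:
    title: str
    curves: list[Series] = field(default_factory=list)


@dataclass
class ReportData:
    title: str
    columns: list[tuple[str, np.ndarray]] = field(default_factory=list)


ExperimentResult = dict  # output id -> PlotData | ReportData


# ---------------------------------------------------------------------------
# Task execution
# ---------------------------------------------------------------------------

def _run_simple_task(spec: SimulationSpec, task, models: dict[str, model_lang.ModelDoc],
                     seed_override: int | None,
                     doc_override: model_lang.ModelDoc | None = None) -> SimulationResult:
    mref = spec.get_model_ref(task.model_ref)
    sim = spec.get_simulation(task.simulation)
    mdoc = doc_override
    if mdoc is None:
        base = models.get(mref.source)
        if base is None:
            raise ValidationError(f"task {task.id!r}: unknown model source"
                                  f" {mref.source!r}")
        mdoc = engine.apply_changes(base, mref.changes)
    sys = engine.compile(mdoc)
    try:
        if sim.kind == "steady_state":
            values = engine.steady_state(sys)
            env = sys.env(0.0, np.array([values[s] for s in sys.state_ids]))
            row = [0.0] + [env[c] for c in sys.output_ids[1:]]
            return SimulationResult(list(sys.output_ids),
                                    np.array([row], dtype=float))
        if sim.algorithm == "gillespie":
            return engine.simulate_ssa(sys, sim, seed=seed_override
                                       if seed_override is not None else sim.seed)
        return engine.simulate_ode(sys, sim)
    except EngineError as exc:
        raise EngineError(f"task {task.id!r}: {exc}") from None


def _run_repeated_task(spec: SimulationSpec, rt: RepeatedTask,
                       models: dict[str, model_lang.ModelDoc],
                       seed_override: int | None) -> list[tuple[float, SimulationResult]]:
    sub = spec.get_task(rt.subtask)
    if isinstance(sub, RepeatedTask):
        raise ValidationError("nested repeated tasks are not supported")
    mref = spec.get_model_ref(sub.model_ref)
    sim = spec.get_simulation(sub.simulation)
    base = models[mref.source]
    base = engine.apply_changes(base, mref.changes)
    results: list[tuple[float, SimulationResult]] = []
    carried = base
    base_seed = seed_override if seed_override is not None else sim.seed
    for i, value in enumerate(rt.values()):
        mdoc = engine.apply_changes(base if rt.reset_model else carried,
                                    [(rt.range_target, value)])
        seed_i = None if base_seed is None else base_seed + i
        res = _run_simple_task(spec, sub, models,
                               seed_override=seed_i, doc_override=mdoc)
        if not rt.reset_model and sim.kind != "steady_state":
            # carry the endpoint state into the next repeat
            carried = engine.apply_changes(carried, [(rt.range_target, value)])
            endpoint = res.rows[-1]
            for cid, val in zip(res.column_ids[1:], endpoint[1:]):
                sp = carried.get_species(cid)
                if sp is not None and not sp.is_boundary:
                    sp.initial_value = float(val)
        results.append((value, res))
    return results


# ---------------------------------------------------------------------------
# Data generators
# ---------------------------------------------------------------------------

def evaluate_data_generator(gen: DataGen, results: dict[str, SimulationResult]):
    """Apply the generator's math elementwise over its tasks' columns."""
    env: dict[str, np.ndarray] = {}
    n_rows = None
    for sym in expr_symbols(gen.math):
        if "." in sym:
            task, name = sym.split(".", 1)
            res = results.get(task)
            if res is None:
                raise ValidationError(f"data generator {gen.id!r} references"
                                      f" unexecuted task {task!r}")
            col = res.time if name == "time" else res.column(name)
        elif sym == "time":
            if not results:
                raise ValidationError("bare `time` with no task results")
            col = next(iter(results.values())).time
        else:
            raise ValidationError(f"unqualified symbol {sym!r} in data generator")
        if n_rows is not None and len(col) != n_rows:
            raise ValidationError(
                f"data generator {gen.id!r} mixes tasks with different row counts")
        n_rows = len(col)
        env[sym] = col
    values = eval_expr(gen.math, env)
    if np.ndim(values) == 0:
        values = np.full(n_rows or 1, float(values))
    return np.asarray(values, dtype=float)


def _gen_tasks(gen: DataGen) -> set[str]:
    return {s.split(".", 1)[0] for s in expr_symbols(gen.math) if "." in s}


# ---------------------------------------------------------------------------
# Whole-experiment execution
# ---------------------------------------------------------------------------

def run_experiment(doc: OmexDocument,
                   seed_override: int | None = None) -> ExperimentResult:
    """Execute every simulation section of a document; return all outputs."""
    doc.validate()
    models: dict[str, model_lang.ModelDoc] = {}
    for section in doc.model_sections():
        mdoc = model_lang.parse_model(section.text)
        models[mdoc.id] = mdoc
        models.setdefault(section.archive_path, mdoc)

    outputs: ExperimentResult = {}
    out_index = 0
    for section in doc.simulation_sections():
        spec = sim_lang.parse_simulation(section.text, known_models=set(models))
        task_results: dict[str, SimulationResult] = {}
        repeat_results: dict[str, list[tuple[float, SimulationResult]]] = {}
        for task in spec.tasks:
            task_results[task.id] = _run_simple_task(spec, task, models, seed_override)
        for rt in spec.repeated_tasks:
            repeat_results[rt.id] = _run_repeated_task(spec, rt, models, seed_override)

        gen_by_id = {g.id: g for g in spec.data_generators}
        for output in spec.outputs:
            out_index += 1
            key = f"{output.title}" if output.title else f"output{out_index}"
            if key in outputs:
                key = f"{key}_{out_index}"
            if output.kind == "plot2d":
                plot = PlotData(title=output.title)
                for label, xg, yg in output.curves:
                    xgen, ygen = gen_by_id[xg], gen_by_id[yg]
                    rep_ids = (_gen_tasks(xgen) | _gen_tasks(ygen)) & set(repeat_results)
                    if rep_ids:
                        rid = next(iter(rep_ids))
                        for value, res in repeat_results[rid]:
                            sub_results = dict(task_results)
                            sub_results[rid] = res
                            xs = evaluate_data_generator(xgen, sub_results)
                            ys = evaluate_data_generator(ygen, sub_results)
                            plot.curves.append(Series(f"{label} ({value:g})", xs, ys))
                    else:
                        xs = evaluate_data_generator(xgen, task_results)
                        ys = evaluate_data_generator(ygen, task_results)
                        plot.curves.append(Series(label, xs, ys))
                outputs[key] = plot
            else:
                report = ReportData(title=output.title)
                for col in output.columns:
                    gen = gen_by_id[col]
                    rep_ids = _gen_tasks(gen) & set(repeat_results)
                    if rep_ids:
                        rid = next(iter(rep_ids))
                        for value, res in repeat_results[rid]:
                            sub_results = dict(task_results)
                            sub_results[rid] = res
                            report.columns.append(
                                (f"{col} ({value:g})",
                                 evaluate_data_generator(gen, sub_results)))
                    else:
                        report.columns.append(
                            (col, evaluate_data_generator(gen, task_results)))
                outputs[key] = report
    return outputs


# ---------------------------------------------------------------------------
# Trajectory comparison
# ---------------------------------------------------------------------------

def compare_expected(result: SimulationResult, expected: SimulationResult,
                     threshold: float = MSE_THRESHOLD) -> ComparisonResult:
    """Columnwise mean-squared-error comparison with a max-MSE criterion.

    The expected table may be on a coarser time grid, as long as every
    expected time appears in the result grid (rows are aligned by time).
    """
    shared = [c for c in expected.column_ids if c != "time"]
    missing = [c for c in shared if c not in result.column_ids]
    if missing:
        raise ValidationError(f"result lacks expected column(s): {missing}")

    if result.rows.shape[0] == expected.rows.shape[0]:
        idx = np.arange(result.rows.shape[0])
    else:
        t_res = result.time
        idx = []
        for te in expected.time:
            j = int(np.argmin(np.abs(t_res - te)))
            if abs(t_res[j] - te) > 1e-9 * max(1.0, abs(te)):
                raise ValidationError(
                    f"expected time {te} not present in result grid")
            idx.append(j)
        idx = np.array(idx)

    per_column: dict[str, float] = {}
    for c in shared:
        diff = result.column(c)[idx] - expected.column(c)
        per_column[c] = float(np.mean(diff ** 2))
    max_mse = max(per_column.values()) if per_column else 0.0
    return ComparisonResult(per_column, max_mse, max_mse < threshold, threshold)


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------

def write_outputs(result: ExperimentResult, directory: str,
                  formats: tuple[str, ...] = ("csv",)) -> list[str]:
    """Write one CSV per output (and optionally a PNG per plot)."""
    os.makedirs(directory, exist_ok=True)
    written: list[str] = []
    for key, data in result.items():
        safe = "".join(ch if ch.isalnum() or ch in "-_." else "_" for ch in key)
        if "csv" in formats:
            path = os.path.join(directory, f"{safe}.csv")
            with open(path, "w", newline="") as fh:
                if isinstance(data, PlotData):
                    header, cols = [], []
                    for s in data.curves:
                        header += [f"{s.label}_x", f"{s.label}_y"]
                        cols += [s.x, s.y]
                else:
                    header = [label for label, _ in data.columns]
                    cols = [v for _, v in data.columns]
                fh.write(",".join(header) + "\r\n")
                n = max((len(c) for c in cols), default=0)
                for i in range(n):
                    fh.write(",".join(repr(float(c[i])) if i < len(c) else ""
                                      for c in cols) + "\r\n")
            written.append(path)
        if "png" in formats and isinstance(data, PlotData):
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots()
            for s in data.curves:
                ax.plot(s.x, s.y, label=s.label)
            ax.set_title(data.title)
            ax.legend(fontsize="small")
            path = os.path.join(directory, f"{safe}.png")
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
    return written
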