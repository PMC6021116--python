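"""Numerical core: compile reaction networks and run simulations.

A :class:`CompiledSystem` holds the ODE right-hand side dx/dt = S^T v(x,p,t)
(stoichiometry matrix times kinetic rate vector) plus rate rules, with
assignment rules re-evaluated before every rate evaluation and before output
capture.  Boundary species and assignment-rule targets are excluded from the
state vector.

Deterministic timecourses use adaptive-step integration (LSODA by default,
BDF for the cvode keyword, or a fixed-step classic Runge-Kutta for rk4).
Events fire on a false->true trigger transition; the crossing is localized
by bisection on the integrator's dense output to |dt| <= 1e-9 x (t_end-t0),
the assignments are applied, and integration restarts.

Stochastic simulation implements the Gillespie direct method with rate laws
read as propensities over copy numbers; trajectories are recorded onto the
requested output grid by last-value-carried-forward and are reproducible
from the seed.

Steady states are found by damped Newton iteration on a finite-difference
Jacobian, seeded by pre-integration; singular Jacobians (conserved moieties)
fall back to integrating until max|dx/dt| converges below tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import EngineError, SteadyStateError, ValidationError
from .expr import Expr, eval_expr
from .model_lang import ModelDoc, assignment_order
from .sim_lang import Simulation

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-12
EVENT_LOCALIZATION_REL = 1e-9
STEADY_STATE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Model editing
# ---------------------------------------------------------------------------

def apply_changes(doc: ModelDoc, changes: list[tuple[str, float]]) -> ModelDoc:
    """Return a copy of ``doc`` with parameter values / species initial
    values overwritten; every other element is shared semantics, fresh data."""
    import copy
    out = copy.deepcopy(doc)
    for target, value in changes:
        sp = out.get_species(target)
        if sp is not None:
            sp.initial_value = value
            continue
        if target in out.parameter_ids():
            out.parameters = [(p, value if p == target else v)
                              for p, v in out.parameters]
            continue
        if target in out.compartment_ids():
            out.compartments = [(c, value if c == target else v)
                                for c, v in out.compartments]
            continue
        raise ValidationError(f"change target {target!r} not found in model {doc.id!r}")
    return out


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

@dataclass
class CompiledSystem:
    doc: ModelDoc
    state_ids: list[str]                 # floating species + rate-rule targets
    initial_state: np.ndarray
    constants: dict[str, float]          # parameters, boundary species, compartments
    stoichiometry: np.ndarray            # reactions x states
    rate_laws: list[Expr]
    assignment_rules: list[tuple[str, Expr]]   # in evaluation order
    rate_rules: list[tuple[str, Expr]]   # aligned to trailing states
    events: list                         # model_lang.Event list
    output_ids: list[str] = field(default_factory=list)

    # -- evaluation helpers -------------------------------------------------
    def env(self, t: float, x: np.ndarray) -> dict:
        e = dict(self.constants)
        for sid, xi in zip(self.state_ids, x):
            e[sid] = xi
        e["time"] = t
        for target, expr in self.assignment_rules:
            e[target] = eval_expr(expr, e)
        return e

    def rates(self, t: float, x: np.ndarray) -> np.ndarray:
        e = self.env(t, x)
        return np.array([eval_expr(r, e) for r in self.rate_laws], dtype=float)

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        e = self.env(t, x)
        v = np.array([eval_expr(r, e) for r in self.rate_laws], dtype=float)
        dx = self.stoichiometry.T @ v if len(v) else np.zeros(len(x))
        for i, (target, expr) in enumerate(self.rate_rules):
            dx[self.state_ids.index(target)] = eval_expr(expr, e)
        return dx

    def output_row(self, t: float, x: np.ndarray) -> list[float]:
        e = self.env(t, x)
        return [t] + [e[c] for c in self.output_ids[1:]]


def compile(doc: ModelDoc) -> CompiledSystem:  # noqa: A001 - domain verb
    """Compile a model into an executable ODE/propensity system."""
    doc.validate()
    assignments = assignment_order(doc)
    assign_targets = {t for t, _ in assignments}
    rate_targets = [t for t, _ in doc.rate_rules]

    state_ids: list[str] = []
    for sp in doc.species:
        if not sp.is_boundary and sp.id not in assign_targets:
            state_ids.append(sp.id)
    for t in rate_targets:
        if t not in state_ids:
            state_ids.append(t)   # rate-rule parameters become states

    reaction_species = set()
    for r in doc.reactions:
        for sid, _ in r.reactants + r.products:
            reaction_species.add(sid)
    for t, _ in doc.assignment_rules:
        sp = doc.get_species(t)
        if sp is not None and t in reaction_species:
            raise ValidationError(
                f"species {t!r} is both reaction-determined and rule-determined")

    constants: dict[str, float] = {}
    for cid, size in doc.compartments:
        constants[cid] = size
    for pid, value in doc.parameters:
        constants[pid] = value
    for sp in doc.species:
        if sp.is_boundary or sp.id in assign_targets:
            constants[sp.id] = sp.initial_value

    init_values: dict[str, float] = {}
    for sp in doc.species:
        init_values[sp.id] = sp.initial_value
    for pid, value in doc.parameters:
        init_values[pid] = value
    # initial assignments (evaluated with everything known so far)
    env0 = dict(constants)
    env0.update(init_values)
    env0["time"] = 0.0
    for target, expr in assignments:
        env0[target] = eval_expr(expr, env0)
    for target, expr in doc.initial_assignments:
        env0[target] = eval_expr(expr, env0)
        init_values[target] = env0[target]
        if target in constants:
            constants[target] = env0[target]

    initial_state = np.array([init_values.get(s, 0.0) for s in state_ids], dtype=float)

    stoich = np.zeros((len(doc.reactions), len(state_ids)))
    index = {s: i for i, s in enumerate(state_ids)}
    for ri, r in enumerate(doc.reactions):
        for sid, st in r.reactants:
            if sid in index:
                stoich[ri, index[sid]] -= st
        for sid, st in r.products:
            if sid in index:
                stoich[ri, index[sid]] += st

    output_ids = ["time"] + state_ids + [t for t, _ in assignments
                                         if t not in state_ids]
    return CompiledSystem(
        doc=doc, state_ids=state_ids, initial_state=initial_state,
        constants=constants, stoichiometry=stoich,
        rate_laws=[r.rate_law for r in doc.reactions],
        assignment_rules=assignments, rate_rules=list(doc.rate_rules),
        events=list(doc.events), output_ids=output_ids)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    column_ids: list[str]            # first column is time
    rows: np.ndarray                 # time-major matrix

    def column(self, cid: str) -> np.ndarray:
        return self.rows[:, self.column_ids.index(cid)]

    @property
    def time(self) -> np.ndarray:
        return self.rows[:, 0]

    def validate(self) -> None:
        if self.rows.shape[1] != len(self.column_ids):
            raise ValidationError("row width does not match column count")
        if np.any(np.diff(self.rows[:, 0]) < 0):
            raise ValidationError("time column must be non-decreasing")


@dataclass
class ComparisonResult:
    per_column_mse: dict[str, float]
    max_mse: float
    passed: bool
    threshold: float = 1e-3


# ---------------------------------------------------------------------------
# Deterministic integration
# ---------------------------------------------------------------------------

def _trigger_state(sys: CompiledSystem, t: float, x: np.ndarray) -> list[bool]:
    e = sys.env(t, x)
    return [bool(eval_expr(ev.trigger, e)) for ev in sys.events]


def _apply_event(sys: CompiledSystem, ev, t: float, x: np.ndarray) -> np.ndarray:
    e = sys.env(t, x)
    new_x = x.copy()
    updates = {target: eval_expr(expr, e) for target, expr in ev.assignments}
    for target, value in updates.items():
        if target in sys.state_ids:
            new_x[sys.state_ids.index(target)] = value
        elif target in sys.constants:
            sys.constants[target] = value
        else:
            raise EngineError(f"event assigns unknown target {target!r}")
    return new_x


def simulate_ode(sys: CompiledSystem, sim: Simulation) -> SimulationResult:
    """Adaptive-step deterministic timecourse with event handling."""
    if sim.kind != "uniform_timecourse":
        raise EngineError("simulate_ode requires a uniform_timecourse simulation")
    rtol = sim.rtol if sim.rtol is not None else DEFAULT_RTOL
    atol = sim.atol if sim.atol is not None else DEFAULT_ATOL
    method = {"lsoda": "LSODA", "cvode": "BDF", "rk4": "RK45"}.get(sim.algorithm)
    if method is None:
        raise EngineError(f"algorithm {sim.algorithm!r} is not deterministic")
    if sim.algorithm == "rk4":
        return _simulate_rk4(sys, sim)

    t0, t_end = sim.t0, sim.t_end
    span = t_end - t0
    grid = np.linspace(t0, t_end, sim.n_points + 1)
    rows: list[list[float]] = []
    x = sys.initial_state.copy()
    t_cur = t0
    grid_idx = 0
    # per spec: triggers already true at t0 do not fire at start
    trig_prev = _trigger_state(sys, t0, x)

    while True:
        try:
            sol = solve_ivp(sys.rhs, (t_cur, t_end), x, method=method,
                            rtol=rtol, atol=atol, dense_output=True)
        except Exception as exc:  # pragma: no cover - integrator internals
            raise EngineError(f"integrator failure at t={t_cur}: {exc}") from None
        if not sol.success:
            raise EngineError(f"integrator failure at t={sol.t[-1]}: {sol.message}")

        event_time = None
        event_obj = None
        # scan internal steps for a trigger transition
        for i in range(1, len(sol.t)):
            ta, tb = sol.t[i - 1], sol.t[i]
            trig_now = _trigger_state(sys, tb, sol.y[:, i])
            fired = [k for k, (p, n) in enumerate(zip(trig_prev, trig_now))
                     if not p and n]
            if fired:
                k = fired[0]
                ev = sys.events[k]
                lo, hi = ta, tb
                tol = EVENT_LOCALIZATION_REL * span
                while hi - lo > tol:
                    mid = 0.5 * (lo + hi)
                    if bool(eval_expr(ev.trigger, sys.env(mid, sol.sol(mid)))):
                        hi = mid
                    else:
                        lo = mid
                event_time, event_obj = hi, ev
                break
            trig_prev = trig_now

        stop_t = event_time if event_time is not None else t_end
        # capture grid points reached before the event / end
        while grid_idx < len(grid) and grid[grid_idx] <= stop_t + 1e-15 * max(1.0, abs(stop_t)):
            tg = grid[grid_idx]
            if event_time is not None and tg > event_time:
                break
            xg = sol.sol(min(max(tg, sol.t[0]), sol.t[-1]))
            if not sim.variable_step_size:
                rows.append(sys.output_row(tg, xg))
            grid_idx += 1
        if sim.variable_step_size:
            for i, ti in enumerate(sol.t):
                if ti > stop_t + 1e-15:
                    break
                if rows and ti <= rows[-1][0]:
                    continue
                rows.append(sys.output_row(ti, sol.y[:, i]))
            if event_time is not None and (not rows or rows[-1][0] < event_time):
                rows.append(sys.output_row(event_time, sol.sol(event_time)))

        if event_time is None:
            break
        x_pre = sol.sol(event_time)
        x = _apply_event(sys, event_obj, event_time, x_pre)
        if sim.variable_step_size:
            rows.append(sys.output_row(event_time, x))
        t_cur = event_time
        trig_prev = _trigger_state(sys, t_cur, x)
        if t_cur >= t_end:
            break

    if not sim.variable_step_size:
        # any grid point skipped past the final event still needs capture
        while grid_idx < len(grid):
            rows.append(sys.output_row(grid[grid_idx], x))
            grid_idx += 1
    else:
        if not rows or rows[-1][0] < t_end:
            pass  # integration loop always reaches t_end above

    result = SimulationResult(list(sys.output_ids), np.array(rows, dtype=float))
    result.validate()
    return result


def _simulate_rk4(sys: CompiledSystem, sim: Simulation) -> SimulationResult:
    """Classic fixed-step RK4 on the output grid (4 substeps per interval)."""
    grid = np.linspace(sim.t0, sim.t_end, sim.n_points + 1)
    x = sys.initial_state.copy()
    rows = [sys.output_row(grid[0], x)]
    trig_prev = _trigger_state(sys, grid[0], x)
    for a, b in zip(grid[:-1], grid[1:]):
        nsub = 4
        h = (b - a) / nsub
        t = a
        for _ in range(nsub):
            k1 = sys.rhs(t, x)
            k2 = sys.rhs(t + h / 2, x + h / 2 * k1)
            k3 = sys.rhs(t + h / 2, x + h / 2 * k2)
            k4 = sys.rhs(t + h, x + h * k3)
            x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        trig_now = _trigger_state(sys, b, x)
        for k, (p, n) in enumerate(zip(trig_prev, trig_now)):
            if not p and n:
                x = _apply_event(sys, sys.events[k], b, x)
        trig_prev = _trigger_state(sys, b, x)
        rows.append(sys.output_row(b, x))
    result = SimulationResult(list(sys.output_ids), np.array(rows, dtype=float))
    result.validate()
    return result


# ---------------------------------------------------------------------------
# Stochastic simulation (Gillespie direct method)
# ---------------------------------------------------------------------------

def simulate_ssa(sys: CompiledSystem, sim: Simulation,
                 seed: int | None = None) -> SimulationResult:
    """Gillespie direct method; rate laws are read as propensities."""
    if sim.kind != "uniform_timecourse":
        raise EngineError("simulate_ssa requires a uniform_timecourse simulation")
    if seed is None:
        seed = sim.seed
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
        warnings.warn(f"no seed given; drew entropy seed {seed}", stacklevel=2)
    rng = np.random.default_rng(seed)

    grid = np.linspace(sim.t0, sim.t_end, sim.n_points + 1)
    x = np.round(sys.initial_state).astype(float)
    t = sim.t0
    rows: list[list[float]] = []
    gi = 0
    trig_prev = _trigger_state(sys, t, x)

    while True:
        props = sys.rates(t, np.maximum(x, 0.0))
        if np.any(props < 0):
            bad = sys.doc.reactions[int(np.argmin(props))].id
            raise EngineError(f"negative propensity in reaction {bad!r} at t={t}")
        a0 = props.sum()
        if a0 <= 0:
            t_next = np.inf
        else:
            t_next = t + rng.exponential(1.0 / a0)
        # record grid points passed before the next firing
        while gi < len(grid) and grid[gi] <= min(t_next, sim.t_end):
            rows.append(sys.output_row(grid[gi], x))
            gi += 1
        if t_next > sim.t_end or not np.isfinite(t_next):
            break
        j = int(np.searchsorted(np.cumsum(props), rng.uniform(0, a0), side="left"))
        j = min(j, len(props) - 1)
        x = x + sys.stoichiometry[j]
        t = t_next
        trig_now = _trigger_state(sys, t, x)
        for k, (p, n) in enumerate(zip(trig_prev, trig_now)):
            if not p and n:
                x = _apply_event(sys, sys.events[k], t, x)
        trig_prev = _trigger_state(sys, t, x)
    while gi < len(grid):
        rows.append(sys.output_row(grid[gi], x))
        gi += 1

    result = SimulationResult(list(sys.output_ids), np.array(rows, dtype=float))
    result.validate()
    return result


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------

def steady_state(sys: CompiledSystem, tol: float = STEADY_STATE_TOL,
                 preintegrate_to: float = 1000.0) -> dict[str, float]:
    """Find x* with max|dx/dt| < tol via damped Newton on an FD Jacobian."""
    x = sys.initial_state.copy()
    if len(x) == 0:
        return {}

    def residual(x_):
        return sys.rhs(0.0, x_)

    # seed with a transient
    try:
        sol = solve_ivp(sys.rhs, (0.0, preintegrate_to), x, method="LSODA",
                        rtol=1e-8, atol=1e-10)
        if sol.success:
            x = sol.y[:, -1]
    except Exception:
        pass

    n = len(x)
    for _ in range(100):
        f = residual(x)
        if np.max(np.abs(f)) < tol:
            return dict(zip(sys.state_ids, x))
        J = np.empty((n, n))
        for j in range(n):
            h = 1e-7 * max(abs(x[j]), 1.0)
            xp = x.copy()
            xp[j] += h
            J[:, j] = (residual(xp) - f) / h
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return _integrate_to_steady(sys, x, tol, preintegrate_to)
        if not np.all(np.isfinite(step)):
            return _integrate_to_steady(sys, x, tol, preintegrate_to)
        # damped line search on the residual norm
        lam = 1.0
        f_norm = np.linalg.norm(f)
        improved = False
        while lam > 1e-6:
            x_new = x + lam * step
            f_new = residual(x_new)
            if np.all(np.isfinite(f_new)) and np.linalg.norm(f_new) < f_norm:
                x = x_new
                improved = True
                break
            lam /= 2
        if not improved:
            return _integrate_to_steady(sys, x, tol, preintegrate_to)
    f = residual(x)
    raise SteadyStateError(
        f"Newton iteration did not converge (residual {np.max(np.abs(f)):.3g})",
        residual=float(np.max(np.abs(f))))


def _integrate_to_steady(sys: CompiledSystem, x: np.ndarray, tol: float,
                         horizon: float) -> dict[str, float]:
    t_span = horizon
    for _ in range(12):
        sol = solve_ivp(sys.rhs, (0.0, t_span), x, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise SteadyStateError(f"integration failed: {sol.message}")
        x = sol.y[:, -1]
        f = sys.rhs(0.0, x)
        if np.max(np.abs(f)) < tol:
            return dict(zip(sys.state_ids, x))
        t_span *= 2
    raise SteadyStateError(
        f"no steady state found by integration (residual {np.max(np.abs(f)):.3g})",
        residual=float(np.max(np.abs(f))))
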