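import numpy as np
import pytest

from omexsim.engine import (apply_changes, compile as compile_model,
                            simulate_ode, simulate_ssa, steady_state)
from omexsim.errors import SteadyStateError, ValidationError
from omexsim.model_lang import parse_model
from omexsim.sim_lang import Simulation

DECAY = "species S = 10\nJ0: S => ; k1*S\nk1 = 0.5"
BIRTH_DEATH = ("species X = 0\nJ0: => X; k_birth\nJ1: X => ; k_death*X\n"
               "k_birth = 10\nk_death = 0.1")


def _sim(**kw):
    defaults = dict(t0=0.0, t_end=2.0, n_points=100, rtol=1e-10, atol=1e-14)
    defaults.update(kw)
    return Simulation("sim", **defaults)


# -- apply_changes ----------------------------------------------------------

def test_apply_changes_parameters_and_species():
    doc = parse_model("species StgPc = 1\nJ0: StgPc => ; kdstg*StgPc\n"
                      "ksstg = 0\nkdstg = 0")
    out = apply_changes(doc, [("ksstg", 0.02), ("kdstg", 0.015), ("StgPc", 0.0)])
    assert dict(out.parameters) == {"ksstg": 0.02, "kdstg": 0.015}
    assert out.get_species("StgPc").initial_value == 0.0
    # original untouched
    assert dict(doc.parameters) == {"ksstg": 0.0, "kdstg": 0.0}


def test_apply_changes_empty_is_equal():
    doc = parse_model(DECAY)
    assert apply_changes(doc, []) == doc


def test_apply_changes_unknown_target():
    with pytest.raises(ValidationError, match="nope"):
        apply_changes(parse_model(DECAY), [("nope", 1.0)])


# -- compile ----------------------------------------------------------------

def test_compile_decay_rhs():
    sys = compile_model(parse_model(DECAY))
    assert sys.state_ids == ["S"]
    np.testing.assert_allclose(sys.rhs(0.0, np.array([10.0])), [-5.0])


def test_boundary_species_excluded_from_state():
    sys = compile_model(parse_model("J0: $U => V; k*U\nU = 3\nk = 1"))
    assert sys.state_ids == ["V"]
    assert sys.constants["U"] == 3.0


def test_assignment_target_reported_not_integrated():
    doc = parse_model("species Stgc = 1\nJ0: Stgc => ; k*Stgc\nk = 1\n"
                      "StgT := 2*Stgc")
    sys = compile_model(doc)
    assert "StgT" not in sys.state_ids
    assert "StgT" in sys.output_ids


def test_closed_system_conserves_total():
    doc = parse_model("species A = 10, B = 0\nJ0: A -> B; k*(A - B)\nk = 1")
    res = simulate_ode(compile_model(doc), _sim(t_end=5.0))
    total = res.column("A") + res.column("B")
    np.testing.assert_allclose(total, 10.0, rtol=1e-8)


# -- deterministic integration ----------------------------------------------

def test_decay_matches_closed_form():
    res = simulate_ode(compile_model(parse_model(DECAY)), _sim())
    S = res.column("S")
    exact = 10.0 * np.exp(-0.5 * res.time)
    np.testing.assert_allclose(S, exact, rtol=1e-6)
    assert abs(S[-1] - 10 * np.exp(-1)) / (10 * np.exp(-1)) < 1e-6


def test_zero_rate_constant_trajectory():
    doc = apply_changes(parse_model(DECAY), [("k1", 0.0)])
    res = simulate_ode(compile_model(doc), _sim())
    np.testing.assert_array_equal(res.column("S"), np.full(101, 10.0))


def test_grid_has_n_plus_one_rows():
    res = simulate_ode(compile_model(parse_model(DECAY)), _sim(n_points=40))
    assert res.rows.shape[0] == 41
    assert res.time[0] == 0.0 and res.time[-1] == 2.0


def test_variable_step_size_output():
    res = simulate_ode(compile_model(parse_model(DECAY)),
                       _sim(variable_step_size=True))
    assert res.time[0] == 0.0 and res.time[-1] == 2.0
    assert np.all(np.diff(res.time) > 0)
    # adaptive grid: not the uniform 101-point grid
    assert res.rows.shape[0] != 101 or not np.allclose(
        res.time, np.linspace(0, 2, 101))


def test_timed_event_matches_piecewise_closed_form():
    doc = parse_model(DECAY + "\nE1: at time >= 5: S = 10")
    res = simulate_ode(compile_model(doc), _sim(t_end=10.0, n_points=200))
    t, S = res.time, res.column("S")
    expected = np.where(t < 5, 10 * np.exp(-0.5 * t),
                        10 * np.exp(-0.5 * (t - 5)))
    # the grid point at exactly t=5 keeps the pre-event value
    mask = ~np.isclose(t, 5.0)
    np.testing.assert_allclose(S[mask], expected[mask], rtol=1e-6, atol=1e-9)


def test_state_trigger_event_localization():
    doc = parse_model(DECAY + "\nE1: at S < 2: S = 10")
    sim = _sim(t_end=10.0, n_points=200, variable_step_size=True)
    res = simulate_ode(compile_model(doc), sim)
    t, S = res.time, res.column("S")
    jumps = np.where(np.diff(S) > 1)[0]
    t_star = t[jumps[0]]
    analytic = 2 * np.log(5.0)          # 10*exp(-0.5 t) = 2
    assert abs(t_star - analytic) <= 1e-9 * 10.0


def test_trigger_true_at_start_does_not_fire():
    doc = parse_model(DECAY + "\nE1: at S > 5: S = 0")
    res = simulate_ode(compile_model(doc), _sim())
    assert res.column("S")[0] == 10.0
    assert np.all(res.column("S") > 3)   # never zeroed


def test_rtol_halving_changes_endpoint_below_comparator_threshold():
    sys = compile_model(parse_model(DECAY))
    r1 = simulate_ode(sys, _sim(rtol=1e-6, atol=1e-12))
    r2 = simulate_ode(sys, _sim(rtol=5e-7, atol=5e-13))
    mse = np.mean((r1.column("S") - r2.column("S")) ** 2)
    assert mse < 1e-3


def test_rate_rule_integration():
    doc = parse_model("X' = 2\nX = 1")
    res = simulate_ode(compile_model(doc), _sim(t_end=3.0))
    np.testing.assert_allclose(res.column("X")[-1], 7.0, rtol=1e-8)


def test_rk4_agrees_with_lsoda():
    sys = compile_model(parse_model(DECAY))
    r1 = simulate_ode(sys, _sim(algorithm="rk4", n_points=200))
    r2 = simulate_ode(sys, _sim(n_points=200))
    np.testing.assert_allclose(r1.column("S"), r2.column("S"), rtol=1e-5)


# -- stochastic simulation --------------------------------------------------

def test_ssa_same_seed_identical():
    sys = compile_model(parse_model(BIRTH_DEATH))
    sim = Simulation("s", t0=0, t_end=50, n_points=50, algorithm="gillespie")
    r1 = simulate_ssa(sys, sim, seed=99)
    r2 = simulate_ssa(sys, sim, seed=99)
    np.testing.assert_array_equal(r1.rows, r2.rows)


def test_ssa_different_seeds_differ():
    sys = compile_model(parse_model(BIRTH_DEATH))
    sim = Simulation("s", t0=0, t_end=50, n_points=50, algorithm="gillespie")
    r1 = simulate_ssa(sys, sim, seed=1)
    r2 = simulate_ssa(sys, sim, seed=2)
    assert not np.array_equal(r1.rows, r2.rows)


def test_ssa_zero_propensities_constant_state():
    sys = compile_model(parse_model("species X = 5\nJ0: X => ; k*X\nk = 0"))
    sim = Simulation("s", t0=0, t_end=10, n_points=10, algorithm="gillespie")
    res = simulate_ssa(sys, sim, seed=0)
    np.testing.assert_array_equal(res.column("X"), np.full(11, 5.0))


def test_ssa_mean_approaches_ode_trajectory():
    """Ensemble mean of a linear birth-death process tracks the ODE."""
    sys = compile_model(parse_model(BIRTH_DEATH))
    sim = Simulation("s", t0=0, t_end=30, n_points=30, algorithm="gillespie")
    runs = np.array([simulate_ssa(sys, sim, seed=s).column("X")
                     for s in range(200)])
    mean = runs.mean(axis=0)
    ode = simulate_ode(sys, Simulation("d", t0=0, t_end=30, n_points=30,
                                       rtol=1e-10, atol=1e-12)).column("X")
    se = runs.std(axis=0, ddof=1) / np.sqrt(200)
    # compare away from t=0 where SE vanishes
    assert np.all(np.abs(mean[5:] - ode[5:]) <= 3 * se[5:] + 1e-9)


# -- steady state ------------------------------------------------------------

def test_steady_state_birth_death():
    values = steady_state(compile_model(parse_model(BIRTH_DEATH)))
    assert values["X"] == pytest.approx(100.0, abs=1e-6)


def test_steady_state_from_fixed_point():
    doc = parse_model("species X = 100\nJ0: => X; k_birth\nJ1: X => ; k_death*X\n"
                      "k_birth = 10\nk_death = 0.1")
    values = steady_state(compile_model(doc))
    assert values["X"] == pytest.approx(100.0, abs=1e-6)


def test_steady_state_matches_long_time_integration():
    sys = compile_model(parse_model(BIRTH_DEATH))
    ss = steady_state(sys)
    res = simulate_ode(sys, Simulation("d", t0=0, t_end=500, n_points=10,
                                       rtol=1e-12, atol=1e-14))
    assert ss["X"] == pytest.approx(res.column("X")[-1], abs=1e-6)


def test_pure_production_has_no_steady_state():
    sys = compile_model(parse_model("species X = 0\nJ0: => X; k\nk = 1"))
    with pytest.raises(SteadyStateError):
        steady_state(sys, preintegrate_to=10.0)
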