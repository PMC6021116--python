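"""Self-contained example documents exercising every toolkit feature.

Each fixture is a complete inline OMEX document that parses, converts to an
archive, and runs without any external input.  They double as the test
corpus: closed-form dynamics (exponential decay), stochastic stationary laws
(birth-death), event handling, parameter scans, multi-instantiation plots,
SBO annotation flow, and the model-variant edit pattern built around a
String-regulation surrogate (synthesis/degradation switches, compartment-
weighted totals, and the N = 1.95^C nuclear-compartment scaling rule).
"""

from __future__ import annotations

from .errors import ValidationError

FIXTURE_NAMES = (
    "decay", "reversible_pair", "birth_death", "event_reset", "scan",
    "stochastic_traces", "two_param_sets", "sbo_demo", "repressilator",
    "case2_edit_pattern",
)

_DECAY = """\
model decay
  species S = 10
  J0: S => ; k1*S
  k1 = 0.5
end

m1 = model decay
sim1 = simulate uniform(0, 2, 100)
sim1.relative_tolerance = 1e-10
sim1.absolute_tolerance = 1e-14
t1 = run sim1 on m1
report time, S
"""

_REVERSIBLE_PAIR = """\
model reversible_pair
  species A = 10, B = 0
  J0: A -> B; k1*(A - B)
  k1 = 1
end

m1 = model reversible_pair
sim1 = simulate uniform(0, 5, 100)
t1 = run sim1 on m1
plot "A/B relaxation" time vs A, B
"""

_BIRTH_DEATH = """\
model birth_death
  species X = 0
  J0: => X; k_birth
  J1: X => ; k_death*X
  k_birth = 10
  k_death = 0.1
end

m1 = model birth_death
sim1 = simulate uniform(0, 100, 200)
sim1.algorithm = gillespie
sim1.seed = 1234
t1 = run sim1 on m1
report time, X
"""

# decay from 10 with k = 0.5; the trigger S < 2 first crosses at
# t* = 2*ln(5), after which S resets to 10 and the cycle repeats
_EVENT_RESET = """\
model event_reset
  species S = 10
  J0: S => ; k1*S
  k1 = 0.5
  E1: at S < 2: S = 10
end

m1 = model event_reset
sim1 = simulate uniform(0, 10, 200)
sim1.relative_tolerance = 1e-10
sim1.absolute_tolerance = 1e-14
t1 = run sim1 on m1
report time, S
"""

_SCAN = """\
model decay
  species S = 10
  J0: S => ; k1*S
  k1 = 0.5
end

m1 = model decay
sim1 = simulate uniform(0, 2, 50)
t1 = run sim1 on m1
t2 = repeat t1 for k1 in uniform(0.1, 1, 5), reset=true
plot "decay scan" t2.time vs t2.S
"""

_STOCHASTIC_TRACES = """\
model birth_death
  species X = 0
  J0: => X; k_birth
  J1: X => ; k_death*X
  k_birth = 10
  k_death = 0.1
  dummy = 0
end

m1 = model birth_death
sim1 = simulate uniform(0, 50, 100)
sim1.algorithm = gillespie
sim1.seed = 7
t1 = run sim1 on m1
t2 = repeat t1 for dummy in [0, 1, 2], reset=true
plot "three traces" t2.time vs t2.X
"""

_TWO_PARAM_SETS = """\
model decay2
  species S = 10
  J0: S => ; k1*S
  k1 = 0.5
end

m1 = model decay2 with k1 = 0.5
m2 = model decay2 with k1 = 1.5
sim1 = simulate uniform(0, 4, 100)
t1 = run sim1 on m1
t2 = run sim1 on m2
plot "two parameter sets" time vs S
"""

_SBO_DEMO = """\
model sbo_demo
  compartment C1 = 1
  C1.sboTerm = SBO:0000290
  species E = 1, P = 0
  E.sboTerm = SBO:0000252
  P.sboTerm = SBO:0000297
  J0: E => P; kcat*E
  J0.sboTerm = SBO:0000176
  kcat = 0.2
end

m1 = model sbo_demo
sim1 = simulate uniform(0, 10, 50)
t1 = run sim1 on m1
report time, E, P
"""

# standard 3-gene negative-feedback ring oscillator; Hill-repressed
# transcription, first-order degradation, linear translation
_REPRESSILATOR = """\
model repressilator
  species m1 = 10, m2 = 0, m3 = 0
  species p1 = 0, p2 = 0, p3 = 0
  J1: => m1; alpha/(1 + p3^n) + alpha0
  J2: => m2; alpha/(1 + p1^n) + alpha0
  J3: => m3; alpha/(1 + p2^n) + alpha0
  J4: m1 => ; m1
  J5: m2 => ; m2
  J6: m3 => ; m3
  J7: => p1; beta*m1
  J8: => p2; beta*m2
  J9: => p3; beta*m3
  J10: p1 => ; beta*p1
  J11: p2 => ; beta*p2
  J12: p3 => ; beta*p3
  alpha = 216
  alpha0 = 0.216
  beta = 5
  n = 2
end

mod1 = model repressilator
sim1 = simulate uniform(0, 100, 500)
t1 = run sim1 on mod1
plot "repressilator" time vs p1, p2, p3
"""

# Surrogate for the model-variant edit pattern: a small mass-action network
# carrying the String-regulation symbols.  The simulation section applies the
# four edits — enable synthesis (ksstg) and degradation (kdstg) of String,
# zero the initial phosphorylated cytoplasmic pool (StgPc), and compute the
# compartment-weighted totals via assignment rules.  N = 1.95^C scales the
# effective number of nuclear compartments with the cycle counter C.
_CASE2 = """\
model case2
  species Stgc = 0, Stgn = 0, StgPc = 1, StgPn = 0
  J0: => Stgc; ksstg
  J1: Stgc => ; kdstg*Stgc
  J2: Stgc -> Stgn; ktr*(Stgc - Stgn)
  J3: StgPc => Stgc; kdp*StgPc
  J4: StgPn => Stgn; kdp*StgPn
  ksstg = 0
  kdstg = 0
  ktr = 0.5
  kdp = 0.1
  E_1 = 0.2
  C = 1
  N := 1.95^C
  StgPT := StgPc + StgPn
  StgT := (1 - N*E_1)*Stgc + N*E_1*Stgn
  StringTotal := StgPT + StgT
end

m1 = model case2 with ksstg = 0.02, kdstg = 0.015, StgPc = 0
sim1 = simulate uniform(0, 50, 100)
t1 = run sim1 on m1
report time, StgT, StringTotal, N
"""

_FIXTURES = {
    "decay": _DECAY,
    "reversible_pair": _REVERSIBLE_PAIR,
    "birth_death": _BIRTH_DEATH,
    "event_reset": _EVENT_RESET,
    "scan": _SCAN,
    "stochastic_traces": _STOCHASTIC_TRACES,
    "two_param_sets": _TWO_PARAM_SETS,
    "sbo_demo": _SBO_DEMO,
    "repressilator": _REPRESSILATOR,
    "case2_edit_pattern": _CASE2,
}


def generate_fixture(name: str) -> str:
    """Return the inline OMEX source for a named fixture document."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise ValidationError(
            f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}") from None
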