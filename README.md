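# omexsim

Author, exchange and execute reproducible dynamical-modeling studies from
a single human-readable text file.

Systems-biology models and the simulation experiments run on them are
exchanged in XML standards — SBML for the reaction network, SED-ML for the
experiment, bundled with a manifest into a COMBINE archive (OMEX, a ZIP
container).  Those formats are excellent for tools and painful for humans.
`omexsim` implements the *inline OMEX* idea: one plain-text document that
holds every model as an Antimony-style `model ... end` block and every
simulation instruction as a PhraSEDML-style statement in the global scope.
The toolkit converts such documents losslessly to and from COMBINE
archives, and executes them directly — deterministic (LSODA/BDF/RK4) and
stochastic (Gillespie direct method) timecourses, steady states
(damped Newton with an integration fallback), discrete events, parameter
scans, and data-generator post-processing such as `log10` axes — so the
archive you share is the study you ran.

At the core of the engine is the standard reaction-network ODE

    dx/dt = Sᵀ v(x, p, t)

with stoichiometry matrix `S`, kinetic laws `v`, boundary species held
fixed, assignment rules evaluated before every rate evaluation, and events
firing on false→true trigger transitions (localized to 1e-9 of the
simulated span).  Trajectory reproductions are judged by the maximum
per-column mean squared error; a reproduction fails when max MSE ≥ 1e-3.

Intended users: modelers who want to author, modify and re-share
COMBINE archives as text, and tool authors who need a compact, fully
testable reference for the SBML/SED-ML/OMEX exchange loop.

## Worked example

Write a document, run it, read the results:

```sh
$ omexsim fixture decay -o decay.omex.txt
$ cat decay.omex.txt
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

$ omexsim run decay.omex.txt --out out
INFO executed 1 output(s) in 0.007 s
INFO wrote out/report1.csv
$ head -2 out/report1.csv; tail -1 out/report1.csv
t1_time,t1_S
0.0,10.0
2.0,3.6787944115770252
```

The model is first-order decay dS/dt = −k1·S with S(0) = 10 and
k1 = 0.5, so the closed form gives S(2) = 10·e^−1 = 3.678794...; the final
CSV row reproduces it to ten significant digits.  `omexsim pack
decay.omex.txt -o decay.omex` produces the equivalent COMBINE archive and
`omexsim unpack decay.omex --to-inline back.txt` recovers the text form.

The same flows are available as a library:

```python
>>> import omexsim as ox
>>> m = ox.parse_model("""
... species X = 0
... J0: => X; k_birth
... J1: X => ; k_death*X
... k_birth = 10
... k_death = 0.1
... """)
>>> ox.steady_state(ox.compile(m))
{'X': 100.00000000000081}
```

(The fixed point of the birth-death network is k_birth/k_death = 100.)

`omexsim fixture <name>` emits ten self-contained example documents —
`decay`, `reversible_pair`, `birth_death`, `event_reset`, `scan`,
`stochastic_traces`, `two_param_sets`, `sbo_demo`, `repressilator`,
`case2_edit_pattern` — covering every supported feature, including SBO
annotation round-tripping and the model-variant edit pattern (parameter
switches, zeroed initial pools, and added assignment rules such as
`N := 1.95^C`).

See `docs/grammar.md` for the two DSL grammars and `docs/methods.md` for
the numerical methods and design decisions.

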