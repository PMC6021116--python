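# Methods

## What the toolkit computes

An inline OMEX document couples two small languages in one text file:
reaction-network models in `model ... end` blocks (an Antimony-style
subset) and experiment statements in the global scope (a PhraSEDML-style
subset).  The toolkit maps each model block to SBML Level 3 Version 1 and
each run of global statements to SED-ML Level 1, bundles them with a
COMBINE manifest into an OMEX ZIP, and performs the inverse conversion, so
a whole archive can be read, edited and re-exported as plain text.  The
same in-memory objects feed an execution engine, so a document is directly
runnable.

## Model semantics

A parsed model compiles to

  dx/dt = Sᵀ v(x, p, t)

where `S` is the reactions-by-states stoichiometry matrix and `v` the
vector of kinetic rate laws.  The state vector holds floating species and
rate-rule targets; boundary species (declared with `$`) and
assignment-rule targets are held out of the state and treated as
constants/derived quantities respectively.  Assignment rules are
topologically sorted and re-evaluated before every rate evaluation and
before every output row, so derived quantities such as compartment-weighted
totals (`StgT`, `StringTotal` in the model-variant fixture) are always
consistent with the current state.  Initial assignments are evaluated once
at t0, after plain value assignments.  Species read from SBML files that
use `initialConcentration` are converted to amounts at read time
(amount = concentration × compartment size at t0); the in-memory model is
always amount-based and units are parsed but ignored in computation.

## Numerical choices

- **Deterministic integration.** `scipy`'s adaptive LSODA is the default
  (`cvode` maps to the BDF implementation, `rk4` to a fixed-step classic
  Runge-Kutta with 4 substeps per output interval).  Default tolerances
  are rtol = 1e-6, atol = 1e-12, overridable per simulation via the
  `relative_tolerance` / `absolute_tolerance` properties.  Output is the
  uniform grid of n+1 points, or the solver's internal steps when
  `variable_step_size = true`.
- **Events.** A trigger that is already true at t0 does not fire; events
  fire on a false→true transition.  The crossing is localized by bisection
  on the integrator's dense output to |Δt| ≤ 1e-9 × (t_end − t0), the
  assignments are applied simultaneously from pre-event values (declaration
  order breaks ties between simultaneous events, for determinism), and
  integration restarts.  Under `variable_step_size` both the pre- and
  post-event rows are emitted at the located time, so the time column is
  non-decreasing rather than strictly increasing at an event.
- **Stochastic simulation.** The Gillespie direct method: total propensity
  a0, exponential waiting time 1/a0, next reaction chosen proportionally to
  its propensity.  Rate laws are read verbatim as propensities over copy
  numbers (no volume conversion — a documented limitation; mass-action laws
  written for concentrations in non-unit volumes will scale accordingly).
  States are recorded onto the requested grid by last-value-carried-forward.
  A run is reproducible from its seed; when no seed is given a fresh
  entropy seed is drawn and reported in a warning so the run can be
  reproduced from logs.  Repeated stochastic tasks derive per-repeat seeds
  as base_seed + repeat_index: reproducible yet independent streams.
- **Steady state.** Damped Newton iteration on a finite-difference
  Jacobian (step 1e-7 scaled by the state magnitude; residual target
  max|dx/dt| < 1e-9), seeded by pre-integration to t = 1000.  A singular
  Jacobian — typical in networks with conserved moieties — triggers a
  fallback that integrates with doubling horizons until the residual
  converges.  Systems with no steady state (e.g. pure production) exhaust
  the horizon doublings and raise a diagnostic carrying the residual norm.
- **Trajectory comparison.** Per-column mean squared error on raw values
  (no per-column normalization), aligned by time when the expected table is
  on a coarser grid; a comparison fails when the maximum column MSE
  reaches 1e-3.  The threshold is exposed as an argument/flag.

## Exchange-format conventions

- Default archive paths are `model{i}.xml` / `experiment{i}.xml` in
  document order; `%antimony` / `%phrasedml` headers override them and are
  emitted whenever a document has more than one section.
- The first SED-ML entry (document order) carries the COMBINE `master`
  flag — an archive needs exactly one executable root.
- Unrecognized archive entries (CSV results, metadata, ...) pass through
  conversion untouched and are reattached on re-export.
- ZIP packing is bit-reproducible: fixed 1980-01-01 timestamps, entries
  sorted by location, manifest self-entry at location ".".
- Algorithm keywords map to KiSAO ids through `data/kisao_map.json`
  (lsoda ↔ KISAO:0000088, cvode ↔ KISAO:0000019, gillespie ↔ KISAO:0000029,
  rk4 ↔ KISAO:0000032; tolerances KISAO:0000209/0000211, seed
  KISAO:0000488).  No normative KiSAO id exists for flagging variable-step
  output; the mapping file records KISAO:0000107 (adaptive time-step
  family) for it, and the table can be overridden per call.
- SED-ML change targets use id-based XPath: `.../@value` for parameters,
  `@initialConcentration|@initialAmount` for species.  `outputStartTime`
  always equals `initialTime` (the DSL subset has no transient-skipping
  syntax).
- SBO annotations are written as `sboTerm` attributes on the annotated
  SBML element and as `<id>.sboTerm = SBO:NNNNNNN` statements in the DSL,
  adjacent to the declaration they annotate.  Only element-level terms are
  supported (terms attached to kinetic laws are out of scope).

## Design decisions in open territory

- The `<id>.sboTerm = SBO:NNNNNNN` statement form mirrors assignment
  syntax; annotation identifiers appear inline next to their elements.
- Event statement syntax is `[id:] at <trigger>: target = expr, ...`.
- Undeclared identifiers in rate laws become parameters with value 0 plus
  a warning, matching the permissive authoring style of the shorthand.
- Unqualified variables in plot/report statements expand over every task
  defined so far — this is what lets one `plot time vs S` draw curves for
  several model instantiations; the expansion happens at parse time so
  serialization round trips are exact.
- `Archive` entry order is canonicalized (sorted by location), so
  `unpack(pack(a))` is the identity on canonicalized archives.

## What the fixture corpus emulates — and what it does not

The ten built-in documents are generated programmatically and cover every
feature: closed-form exponential decay (deterministic accuracy), a linear
birth-death process whose stationary law is Poisson(k_birth/k_death)
(stochastic correctness), an event-reset oscillator with an analytic
trigger time, a five-point parameter scan, repeated stochastic traces, two
parameter sets over one model, SBO annotations, the standard three-gene
repressor-ring oscillator, and a surrogate for the String-regulation
model-variant edit pattern (parameters `ksstg`, `kdstg`, species `StgPc`,
rules for `StgT`, `StringTotal` and `N = 1.95^C`).  The surrogate's
dynamics are simple mass-action: it tests that the edits are expressible
and survive the exchange formats, not the original model's numerics.
Consequently, passing tests demonstrate correctness of the machinery on
small, well-conditioned networks; they say nothing about performance or
stiffness robustness on hundred-reaction models, and the published
case-study archives (available from BioModels) are not bundled, so their
trajectories are not reproduced here.

Problem sizes used by the shipped checks: timecourses of 50–500 output
points on models with ≤ 12 reactions; stochastic ensembles of 200
replicates of ~2000 jump events each; golden regression tables are stored
downsampled to ~21 rows per output.

## Known limitations

- No algebraic rules, event delays, fast reactions, function definitions,
  hierarchical models or SBML packages; these raise structured
  "unsupported feature" diagnostics rather than being silently dropped.
- No nested repeated tasks, functional ranges, 3-D plots, bifurcation
  analysis or parameter fitting.
- SSA treats species values as copy numbers directly.
- CellML is out of scope.
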