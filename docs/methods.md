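# Methods

## Model and problem

A Boolean network is a directed graph `G = (V, F)` with internal nodes
`v₁…v_n`, each carrying a state `v_i(t) ∈ {0,1}` and one update function
`f_i` over AND/OR/NOT of its regulators, evaluated synchronously:
`v_i(t+1) = f_i(states at t)`.  External nodes `u₁…u_m` have no update
function and no incoming edges; their values are assigned freely at each
step.  A control problem is `(G, v⁰, v^τ, τ)`: find assignments
`u⁰…u^{τ−1}` such that the internal state at time τ equals `v^τ`, or prove
none exists.  An assignment at time τ itself cannot influence `v^τ`, so
control sequences have exactly τ entries; input files carrying a trailing
row are accepted with a warning.  Desired states may mark nodes as
don't-care (`-`), which relaxes the horizon constraint for those nodes.

Everything is exact and deterministic: no sampling, no heuristics.  The
solver's contract is that its decision always equals brute-force
enumeration, and that any reported sequence passes forward-simulation
verification before it is returned.

## The solver

**Decomposition.** The dependency graph has an edge `j → i` iff `j`
occurs syntactically in `f_i` (an occurrence counts even if logically
vacuous — the graph is structural).  Its SCCs are computed (via networkx)
and ordered topologically; among valid orders, ties are broken by the
smallest declared-node index of each component, so runs are reproducible.
Components are classified as *simple non-branching* (single node, at most
one successor outside itself), *branching single* (single node, two or
more outside successors) or *multi-node* (≥ 2 members).  A self-loop
neither makes a node multi-node nor counts toward branching: its effect on
correctness is absorbed by the verification step below.  Weakly connected
groups of the dependency graph share no constraints and are solved
independently; this is what makes the solver's work *additive* across
independent subnetworks where a monolithic DP would be multiplicative.

**Attainability tables.** For each node and time the solver maintains
ϒᵇ_v(t): whether value `b` is attainable at `t` under some control choice
given all upstream fixings.  Simple components are filled forward by
existential quantification over the regulator values allowed at `t−1`; a
free external has both values attainable at every `t`; the horizon
constraint is checked the moment a column τ is complete, so hopeless
configurations are rejected before any enumeration downstream.  A
constant-node pre-pass (constant functions, input-free nodes, pure
self-copies, plus the closure under partial evaluation) rejects instances
whose desired state conflicts with a provably frozen node before the
decomposition is even consulted; eventually-constant nodes (constant from
some onset `T ≥ 1`, like a node copying the negation of a frozen one) are
tracked separately from frozen-at-all-`t` nodes so early rejection is only
applied where provably correct.

**Hard components.** Branching and multi-node components whose ϒ entries
are genuinely two-valued somewhere are enumerated.  Candidates come from a
per-component backward DP (the classic `D[state, t]` recursion restricted
to the component) in which upstream nodes act as time-indexed *allowed
value sets* — singletons where a component is already fixed, `{0,1}` for a
free external — intersected layer-by-layer with forward reachability from
the initial restriction.  The intersection means every feasible state has
an admissible predecessor and successor, so candidate trajectories are
read off as paths through the layered edge relation.  Candidates are
ordered by binary counting on the encoded member states with `t = 0` least
significant (members little-endian in declared order); for a free external
over τ = 3 this yields the canonical 16-row table whose row #2 is
`(1,0,0,0)`.  The search fixes candidates one at a time and recurses into
downstream components, backtracking on failure.  A branching node whose ϒ
column is single-valued everywhere creates no cross-dependency and is
handled sequentially, without enumeration.

**Extraction.** Per-node ϒ entries over-approximate *joint* attainability
across time (the classic branching pitfall: two consumers of one regulator
can each be satisfiable but jointly contradictory; with self-loops the
same can happen across time steps).  The solver therefore never decides
"solvable" from ϒ alone.  Once every component is processed it runs a
backward regression search: the desired values at τ are demands
`(node, t, bit)`; resolving an internal demand picks a regulator
assignment, allowed by the ϒ sets at `t−1`, that produces the demanded bit
and demands those regulator values in turn; demands ground out at the
initial state and at the externals.  All witness choices are explored with
backtracking, so the search is *complete* for the current fixing: it fails
only when that fixing is genuinely unrealizable, which correctly triggers
the next candidate rather than a wrong answer.  By induction over time,
forward simulation of the found external assignments reproduces every
demanded value, so verification cannot fail; it is asserted anyway, and a
failure would raise, never mis-report.  (An alternative design —
reclassifying a component as hard when extraction stalls and re-searching
— is unnecessary under a complete regression search.)

**Resource caps.** Candidate enumeration and the regression search count
their work; exceeding a cap (defaults: 10⁷ candidates, 10⁷ regression
steps; full-network DP refuses n > 22) raises a distinct resource error
rather than returning a decision.  Unconstrained-at-τ groups are satisfied
by any controls and skip the search entirely.

## Minimal-switching variant

Among valid sequences, `minimize_switching` returns one minimizing
`Σ_u Σ_{t=1..τ−1} [u(t) ≠ u(t−1)]` — the number of on/off flips of the
intervention protocol.  It builds the forward-reachable state layers from
`v⁰` (memoized compiled transitions), then a backward cost-to-go table
over `(state, t, previous control)` where a transition costs the Hamming
distance between consecutive control vectors; reconstruction walks forward
choosing at each step the lexicographically smallest control (declared
external order, earlier steps more significant) that attains the optimum,
so ties break on the concatenated bit-string.  Exactness is tested against
plain enumeration of all sequences on small instances.

## Baselines and oracle

`datta_solve` is the full-network backward DP over all `2^n` states
(`D[s, τ] = 1` iff `s` is desired; `D[s, t] = 1` iff some control leads to
a marked state), kept as an independent exact method and cross-checked
against the solver on every random-suite instance.  `brute_force_solve`
enumerates all `2^{m·τ}` control sequences bit-parallel: sequence index
`k` assigns external `j` at time `t` the bit `k >> (t·m + j)`, and each
node's state across all sequences is one big-integer mask, so a single
sweep of the network decides every sequence; the mask route is itself
validated against per-sequence simulation in the tests, keeping the two
oracle routes independent.

## Synthetic instances

The generator emulates the structural regime the solver targets: sparse
random wiring (`edge_density`, default 0.3, capped at
`max_inputs_per_node = 3` regulators) with a planted cycle fixing a lower
bound on the largest SCC (default 2 — real regulatory networks have small
SCCs, and the achieved size is reported).  Update functions are random
AND/OR/NOT trees in which every sampled regulator occurs.  Initial states
are uniform; with probability ½ the desired state is read off a simulated
trajectory under random controls (guaranteeing solvable instances occur)
and otherwise drawn uniformly (making unsolvable ones common), so the
validation suites exercise both outcomes; the realized split is roughly
half and half at the defaults.  Identical seeds reproduce byte-identical
instance files.  What the generator does *not* emulate: the in/out-degree
skew, canalyzing-function bias and large weakly-coupled cores of curated
biological models — passing the random suites shows exactness of the
decision procedure, not biological realism of the inputs.

## Packaged fixtures

The Drosophila segment-polarity subnetwork (15 internal nodes, controls
U1–U3, τ = 6 problem) is transcribed rule-for-rule; names are
case-sensitive (`wg` mRNA vs `WG` protein).  The four-node didactic
network realizes the published prose semantics — `u = 1` forces
`(v1, v2) = (1, 0)`, `u = 0` exchanges the pair — as
`v1' = u ∨ (¬u ∧ v2)`, `v2' = ¬u ∧ v1`; its published diagram-only
formulas are not recoverable, but every packaged expectation keys on the
formula-independent trajectories.  `v4`'s initial value is unpublished and
set to 0; nothing depends on it.  The didactic control problem takes as
its desired state the state actually reached under `u = (1,0,0)`, under
which the search fixes candidate row #2 — reproducing the worked ϒ tables
cell-for-cell.  The T-cell receptor model ships as its 40-row
initial/desired state table only (τ = 5 metadata); its wiring is
published only as a figure and is deliberately not reconstructed.

## Problem sizes in the validation suites

The random cross-validation suites use n ≤ 8 internal nodes, m ≤ 2
externals and τ ≤ 5 (200 instances for the three-way agreement check, 40
for the switching optimum, 60 for the DP baseline), sizes at which the
naive references are comfortably exhaustive while still covering all
component categories; the Drosophila horizon profile enumerates up to
2¹⁸ sequences per horizon via the bit-parallel oracle.

## Known limitations

* Worst-case time is still exponential: a network that is one big SCC
  degenerates to the full-state DP (inside one component), and many
  interdependent branching components multiply candidate counts; the caps
  turn this into an explicit resource error.
* The regression search can in principle backtrack exponentially over
  witness choices; the ϒ pruning makes this rare at regulatory-network
  fan-ins, and the step cap bounds it.
* Only synchronous, deterministic updates are modeled — no asynchronous
  or probabilistic semantics, no attractor/basin analysis, no per-step
  control costs beyond switch counting.
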