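"""SCC-guided exact solver for the Boolean network control problem.

Strategy
--------
Components of the regulatory dependency graph are processed in topological
order, independently within each weakly connected group:

* *Simple non-branching* components (single node, at most one consumer) are
  never enumerated.  Their per-time attainability sets — the ϒ table entries
  ϒ^b_v(t) — are filled forward by existential quantification over the
  input values their regulators' ϒ entries allow, and the horizon constraint
  is checked as soon as the column τ is known (early rejection).
* *Hard* components (branching single nodes and multi-node SCCs) whose ϒ
  entries are genuinely two-valued somewhere are enumerated: the candidate
  trajectories consistent with the component's own dynamics, the upstream
  fixings and the horizon restriction (computed by the per-component
  backward DP) are fixed one by one, recursing into downstream components
  and backtracking on failure.  A free external with two or more consumers
  enumerates all ``2^(τ+1)`` bit sequences in binary-counting order with
  ``t = 0`` as the least significant position, so sequence #2 over τ = 3 is
  ``(1, 0, 0, 0)``.

Because per-node ϒ entries over-approximate *joint* attainability across
time, a configuration in which every constraint looks satisfiable may still
be unrealizable.  The solver therefore never reports success from ϒ alone:
a complete backward regression search turns the constraints into concrete
witness assignments (backtracking over the input combinations that realize
each demanded value), and only a sequence that passes forward-simulation
verification is returned.  Failure of that search is a correct reason to
backtrack to the next candidate, which keeps the decision exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .datta import datta_component
from .decompose import (
    Category,
    Component,
    constant_profile,
    dependency_graph,
    strongly_connected_components,
    weakly_connected_groups,
)
from .expr import evaluate
from .network import (
    BooleanNetwork,
    ControlProblem,
    ControlSequence,
    NetworkValidationError,
    compile_step,
    verify_control,
)

__all__ = [
    "SolveResult",
    "SolverStats",
    "ResourceCapError",
    "GammaTable",
    "enumerate_component_sequences",
    "gamma_simple",
    "solve",
    "minimize_switching",
]


class ResourceCapError(RuntimeError):
    """A configured enumeration or search cap was exceeded (not a decision!)."""


@dataclass
class SolverStats:
    states_enumerated: int = 0
    backtracks: int = 0
    components: int = 0
    multi_node_components: int = 0
    candidate_counts: dict[str, int] = field(default_factory=dict)
    resolve_steps: int = 0

    def as_dict(self) -> dict:
        return {
            "states_enumerated": self.states_enumerated,
            "backtracks": self.backtracks,
            "components": self.components,
            "multi_node_components": self.multi_node_components,
            "candidate_counts": dict(self.candidate_counts),
            "resolve_steps": self.resolve_steps,
        }


@dataclass(frozen=True)
class GammaTable:
    """ϒ^b_v(t) for all nodes/values/times: entry true iff value attainable."""

    entries: Mapping[tuple[str, int, int], bool]

    def __call__(self, node: str, b: int, t: int) -> bool:
        return self.entries[(node, b, t)]


@dataclass(frozen=True)
class ComponentStateSpace:
    """Ordered candidate trajectories for one component over t = 0..τ."""

    component: Component
    candidates: tuple[tuple[Mapping[str, int], ...], ...]

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass(frozen=True)
class SolveResult:
    solvable: int
    controls: ControlSequence | None
    verified: int
    stats: SolverStats
    gamma: GammaTable | None = None


# ---------------------------------------------------------------------------
# ϒ machinery


def gamma_simple(
    node: str,
    network: BooleanNetwork,
    allowed: Mapping[str, list[set[int]]],
    t: int,
) -> tuple[bool, bool]:
    """(ϒ^0, ϒ^1) of ``node`` at ``t+1`` by existential quantification.

    A value ``b`` is attainable at ``t+1`` iff some combination of regulator
    values, each allowed by its ϒ entries at ``t``, makes the update
    function produce ``b``.
    """
    f = network.functions[node]
    inputs = network.inputs_of(node)
    for x in inputs:
        if x not in allowed or len(allowed[x]) <= t:
            raise NetworkValidationError(f"ϒ entries for regulator {x!r} at t={t} missing")
    seen0 = seen1 = False
    for combo in itertools.product(*(sorted(allowed[x][t]) for x in inputs)):
        if evaluate(f, dict(zip(inputs, combo))):
            seen1 = True
        else:
            seen0 = True
        if seen0 and seen1:
            break
    return seen0, seen1


def _fill_simple(
    node: str,
    network: BooleanNetwork,
    allowed: dict[str, list[set[int]]],
    initial: Mapping[str, int],
    tau: int,
) -> None:
    """Fill ``allowed[node]`` for t = 0..τ from the regulators' entries."""
    if node in network.external:
        allowed[node] = [{0, 1} for _ in range(tau + 1)]
        return
    # register the growing list up front so a self-loop node reads its own
    # already-computed earlier columns (e.g. Drosophila's SLP, wg)
    sets: list[set[int]] = [{int(initial[node])}]
    allowed[node] = sets
    for t in range(tau):
        has0, has1 = gamma_simple(node, network, allowed, t)
        sets.append(({0} if has0 else set()) | ({1} if has1 else set()))


# ---------------------------------------------------------------------------
# candidate enumeration


def _trajectory_key(encs: Sequence[int], width: int) -> int:
    # binary counting with t=0 least significant (row #2 for an external = 1,0,0,0)
    return sum(e << (width * t) for t, e in enumerate(encs))


def enumerate_component_sequences(
    component: Component,
    network: BooleanNetwork,
    allowed: Mapping[str, list[set[int]]],
    initial: Mapping[str, int],
    desired: Mapping[str, int | None],
    tau: int,
    *,
    max_candidates: int = 10_000_000,
) -> ComponentStateSpace:
    """All candidate per-time trajectories of a component, in stable order.

    A single unconstrained external yields all ``2^(τ+1)`` bit sequences;
    any other component yields exactly the trajectories admitted by the
    per-component DP under the current upstream fixings.  The order is
    binary counting on the encoded member states with ``t = 0`` least
    significant (members encoded little-endian in declared node order).
    """
    members = component.members
    if len(members) == 1 and members[0] in network.external:
        u = members[0]
        cands = tuple(
            tuple({u: (code >> t) & 1} for t in range(tau + 1))
            for code in range(1 << (tau + 1))
        )
        if len(cands) > max_candidates:
            raise ResourceCapError("external candidate space exceeds cap")
        return ComponentStateSpace(component=component, candidates=cands)

    dp = datta_component(
        members,
        network,
        allowed,
        initial,
        {v: desired.get(v) for v in members},
        tau,
    )
    width = len(members)
    paths: list[tuple[int, ...]] = []

    def extend(prefix: list[int], t: int) -> None:
        if len(paths) > max_candidates:
            raise ResourceCapError("component candidate space exceeds cap")
        if t == tau:
            paths.append(tuple(prefix))
            return
        for nxt in sorted(dp.edges[t].get(prefix[-1], ())):
            prefix.append(nxt)
            extend(prefix, t + 1)
            prefix.pop()

    for start in sorted(dp.feasible[0]):
        extend([start], 0)
    paths.sort(key=lambda p: _trajectory_key(p, width))
    cands = tuple(
        tuple(dp.state_values(enc) for enc in path) for path in paths
    )
    return ComponentStateSpace(component=component, candidates=cands)


# ---------------------------------------------------------------------------
# extraction: backward demand regression


class _Extractor:
    """Complete backtracking search realizing demanded (node, t, bit) values.

    Demands are resolved latest-time-first; resolving an internal demand at
    ``t > 0`` picks a regulator assignment allowed by the ϒ sets that
    produces the demanded bit and recursively demands those regulator
    values at ``t - 1``.  All witness choices are explored, so the search
    fails only when the current component fixing is genuinely unrealizable.
    """

    def __init__(
        self,
        network: BooleanNetwork,
        allowed: Mapping[str, list[set[int]]],
        initial: Mapping[str, int],
        stats: SolverStats,
        max_steps: int,
    ):
        self.network = network
        self.allowed = allowed
        self.initial = initial
        self.stats = stats
        self.max_steps = max_steps
        self.node_index = {name: i for i, name in enumerate(network.node_order)}

    def run(self, seeds: Sequence[tuple[str, int, int]]) -> dict[tuple[str, int], int] | None:
        assigned: dict[tuple[str, int], int] = {}
        if self._resolve(list(seeds), assigned):
            return assigned
        return None

    def _resolve(self, queue: list[tuple[str, int, int]], assigned) -> bool:
        trail: list[tuple[str, int]] = []

        def undo() -> None:
            for key in trail:
                del assigned[key]

        while queue:
            self.stats.resolve_steps += 1
            if self.stats.resolve_steps > self.max_steps:
                raise ResourceCapError("extraction search exceeded the step cap")
            queue.sort(key=lambda d: (-d[1], self.node_index[d[0]]))
            node, t, bit = queue.pop(0)
            prev = assigned.get((node, t))
            if prev is not None:
                if prev != bit:
                    undo()
                    return False
                continue
            if bit not in self.allowed[node][t]:
                undo()
                return False
            assigned[(node, t)] = bit
            trail.append((node, t))
            if node in self.network.external:
                continue
            if t == 0:
                if int(self.initial[node]) != bit:
                    undo()
                    return False
                continue
            inputs = self.network.inputs_of(node)
            f = self.network.functions[node]
            found = False
            for combo in itertools.product(
                *(sorted(self.allowed[x][t - 1]) for x in inputs)
            ):
                if evaluate(f, dict(zip(inputs, combo))) != bit:
                    continue
                extra = [(x, t - 1, b) for x, b in zip(inputs, combo)]
                if self._resolve(queue + extra, assigned):
                    found = True
                    break
            if found:
                return True
            undo()
            return False
        return True


# ---------------------------------------------------------------------------
# the solver


def _group_search(
    network: BooleanNetwork,
    comps: list[Component],
    initial: Mapping[str, int],
    desired: Mapping[str, int | None],
    tau: int,
    stats: SolverStats,
    max_states: int,
    max_resolve_steps: int,
) -> tuple[dict[tuple[str, int], int], dict[str, list[set[int]]]] | None:
    """Solve one weakly connected group; returns (witness values, ϒ sets) or None."""
    allowed: dict[str, list[set[int]]] = {}

    constrained = any(desired.get(v) is not None for c in comps for v in c.members)

    def process(idx: int) -> dict[tuple[str, int], int] | None:
        if idx == len(comps):
            seeds = [
                (v, tau, desired[v])
                for c in comps
                for v in c.members
                if v in network.internal and desired.get(v) is not None
            ]
            extractor = _Extractor(
                network, allowed, initial, stats, max_resolve_steps
            )
            return extractor.run(seeds)
        comp = comps[idx]
        # Fill ϒ sequentially first; hard components with single-valued ϒ
        # everywhere need no enumeration either (a branching node that can
        # attain only one state per step creates no cross-dependency).
        saved = {}
        single_fill_ok = True
        if comp.category is Category.MULTI_NODE:
            single_fill_ok = False
        else:
            node = comp.members[0]
            _fill_simple(node, network, allowed, initial, tau)
            multivalued = any(len(s) > 1 for s in allowed[node])
            if comp.category is Category.BRANCHING_SINGLE and multivalued:
                del allowed[node]
                single_fill_ok = False
            elif node in network.internal and desired.get(node) is not None:
                if desired[node] not in allowed[node][tau]:
                    del allowed[node]
                    return None  # early rejection at the horizon
        if single_fill_ok:
            node = comp.members[0]
            result = process(idx + 1)
            if result is None:
                del allowed[node]
            return result

        # hard path: enumerate candidate trajectories
        space = enumerate_component_sequences(
            comp, network, allowed, initial, desired, tau, max_candidates=max_states
        )
        stats.candidate_counts[str(comp)] = max(
            stats.candidate_counts.get(str(comp), 0), len(space)
        )
        for cand in space.candidates:
            if stats.states_enumerated >= max_states:
                raise ResourceCapError("enumerated-state cap exceeded")
            stats.states_enumerated += 1
            for v in comp.members:
                allowed[v] = [{int(cand[t][v])} for t in range(tau + 1)]
            result = process(idx + 1)
            if result is not None:
                return result
            stats.backtracks += 1
            for v in comp.members:
                del allowed[v]
        return None

    if not constrained:
        # nothing in this group is constrained at the horizon: any controls
        # work, so only the (informational) ϒ sets are produced
        for comp in comps:
            for v in comp.members:
                if v in network.external:
                    allowed[v] = [{0, 1} for _ in range(tau + 1)]
                elif len(comp.members) == 1:
                    _fill_simple(v, network, allowed, initial, tau)
                else:
                    allowed[v] = [{int(initial[v])}] + [{0, 1} for _ in range(tau)]
        return {}, allowed

    witness = process(0)
    if witness is None:
        return None
    return witness, allowed


def solve(
    problem: ControlProblem,
    *,
    find_sequence: bool = True,
    minimize_switching: bool = False,
    max_states: int = 10_000_000,
    max_resolve_steps: int = 10_000_000,
) -> SolveResult:
    """Decide the control problem and (by default) extract a verified sequence.

    The returned decision always equals the brute-force answer; a reported
    sequence has passed :func:`verify_control`.  Exceeding a resource cap
    raises :class:`ResourceCapError` rather than returning a wrong decision.
    """
    if minimize_switching:
        return _minimize_switching_impl(problem, max_states=max_states)

    net = problem.network
    tau = problem.horizon
    stats = SolverStats()
    initial = {v: int(problem.initial.values[v]) for v in net.internal}
    desired = dict(problem.desired.values)

    if tau == 0:
        ok = problem.desired_matches(initial)
        controls = ControlSequence(assignments=()) if ok else None
        return SolveResult(int(ok), controls, int(ok), stats, _trivial_gamma(net, initial))

    # early rejection on provably constant nodes, before any enumeration
    for v, (bit, onset) in constant_profile(net, problem.initial).items():
        want = desired.get(v)
        if want is not None and tau >= onset and want != bit:
            return SolveResult(0, None, 0, stats, None)

    graph = dependency_graph(net)
    components = strongly_connected_components(graph, net)
    stats.components = len(components)
    stats.multi_node_components = sum(
        1 for c in components if c.category is Category.MULTI_NODE
    )
    groups = weakly_connected_groups(graph, components, net)

    gamma_entries: dict[tuple[str, int, int], bool] = {}
    witness_all: dict[tuple[str, int], int] = {}
    for comps in groups:
        outcome = _group_search(
            net, comps, initial, desired, tau, stats, max_states, max_resolve_steps
        )
        if outcome is None:
            return SolveResult(0, None, 0, stats, None)
        witness, allowed = outcome
        witness_all.update(witness)
        for v in (m for c in comps for m in c.members):
            sets = allowed.get(v)
            for t in range(tau + 1):
                if sets is not None:
                    bits = sets[t]
                elif v in net.internal and t == 0:
                    bits = {initial[v]}
                else:
                    bits = {0, 1}
                gamma_entries[(v, 0, t)] = 0 in bits
                gamma_entries[(v, 1, t)] = 1 in bits

    gamma = GammaTable(entries=gamma_entries)
    if not find_sequence:
        return SolveResult(1, None, 0, stats, gamma)

    assignments = tuple(
        {u: witness_all.get((u, t), 0) for u in net.external} for t in range(tau)
    )
    controls = ControlSequence(assignments=assignments)
    if not verify_control(problem, controls):  # pragma: no cover - exactness guard
        raise AssertionError(
            "internal inconsistency: extracted sequence failed verification"
        )
    return SolveResult(1, controls, 1, stats, gamma)


def _trivial_gamma(net: BooleanNetwork, initial: Mapping[str, int]) -> GammaTable:
    entries = {}
    for v in net.internal:
        entries[(v, 0, 0)] = initial[v] == 0
        entries[(v, 1, 0)] = initial[v] == 1
    for u in net.external:
        entries[(u, 0, 0)] = True
        entries[(u, 1, 0)] = True
    return GammaTable(entries=entries)


# ---------------------------------------------------------------------------
# minimal-switching variant


def _minimize_switching_impl(
    problem: ControlProblem, *, max_states: int = 10_000_000
) -> SolveResult:
    """Among all valid sequences, minimize adjacent-time control flips.

    Forward layered reachability from the initial state, then a backward
    cost-to-go table over (state, t, previous control); reconstruction picks
    at each step the lexicographically smallest control (declared external
    order, earlier time more significant) that attains the optimum, so ties
    break on the concatenated bit-string.
    """
    base = solve(problem, find_sequence=True)
    if not base.solvable or problem.horizon == 0:
        return base
    net = problem.network
    tau = problem.horizon
    step_fn = compile_step(net)
    controls_domain = list(itertools.product((0, 1), repeat=net.m))

    init = tuple(int(b) for b in problem.initial.as_tuple(net.internal))
    layers: list[set[tuple[int, ...]]] = [{init}]
    trans: list[dict[tuple[tuple[int, ...], tuple[int, ...]], tuple[int, ...]]] = []
    for t in range(tau):
        nxt: set[tuple[int, ...]] = set()
        tmap: dict = {}
        if len(layers[t]) * len(controls_domain) > max_states:
            raise ResourceCapError("reachable layer exceeds the state cap")
        for s in layers[t]:
            for c in controls_domain:
                s2 = step_fn(s, c)
                tmap[(s, c)] = s2
                nxt.add(s2)
        trans.append(tmap)
        layers.append(nxt)

    wanted = tuple(problem.desired.values[v] for v in net.internal)
    INF = float("inf")

    def matches(s: tuple[int, ...]) -> bool:
        return all(w is None or s[i] == w for i, w in enumerate(wanted))

    # cost-to-go J[t][(state, prev_control)]; at t = τ keyed by state alone
    J: list[dict] = [dict() for _ in range(tau + 1)]
    for s in layers[tau]:
        J[tau][s] = 0 if matches(s) else INF
    def flip_cost(prev, c) -> int:
        # per-external flips: the switching objective is a sum over nodes
        return 0 if prev is None else sum(a != b for a, b in zip(prev, c))

    for t in range(tau - 1, -1, -1):
        for s in layers[t]:
            for prev in ([None] if t == 0 else controls_domain):
                best = INF
                for c in controls_domain:
                    cost = flip_cost(prev, c)
                    s2 = trans[t][(s, c)]
                    tail = J[t + 1][s2] if t + 1 == tau else J[t + 1].get((s2, c), INF)
                    if tail == INF:
                        continue
                    best = min(best, cost + tail)
                J[t][(s, prev)] = best

    total = J[0][(init, None)]
    assert total != INF  # solvable was already established
    # lexicographic reconstruction
    seq: list[tuple[int, ...]] = []
    s, prev = init, None
    remaining = total
    for t in range(tau):
        for c in controls_domain:  # lexicographic order over external bits
            cost = flip_cost(prev, c)
            s2 = trans[t][(s, c)]
            tail = J[t + 1][s2] if t + 1 == tau else J[t + 1].get((s2, c), INF)
            if tail != INF and cost + tail == remaining:
                seq.append(c)
                remaining -= cost
                s, prev = s2, c
                break
        else:  # pragma: no cover
            raise AssertionError("minimal-switching reconstruction failed")

    controls = ControlSequence(
        assignments=tuple(
            {u: c[j] for j, u in enumerate(net.external)} for c in seq
        )
    )
    assert verify_control(problem, controls)
    stats = base.stats
    stats.candidate_counts["switching"] = int(total)
    return SolveResult(1, controls, 1, stats, base.gamma)


def minimize_switching(problem: ControlProblem, **kw) -> SolveResult:
    """Convenience wrapper for :func:`solve` with switching minimization."""
    return _minimize_switching_impl(problem, **kw)
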