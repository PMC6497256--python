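"""Backward dynamic programming over explicit state spaces.

Two uses.  As a standalone baseline, :func:`datta_solve` fills the classic
table ``D[state, t]`` over *all* ``2^n`` internal states backward from the
horizon: ``D[s, τ] = 1`` iff ``s`` is the desired state, and ``D[s, t] = 1``
iff some control value leads from ``s`` to a marked state at ``t+1``; the
problem is solvable iff ``D[v^0, 0] = 1``.  Inside the SCC solver,
:func:`datta_component` runs the same backward recursion restricted to one
component, whose inputs from already-processed upstream components are
per-time *allowed value sets* (singletons for fixed trajectories, {0,1} for
a free external), intersected with forward reachability from the initial
restriction — which is what collapses a component's state space to a
single state per time step once upstream choices are fixed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

from .expr import evaluate
from .network import (
    BooleanNetwork,
    ControlProblem,
    ControlSequence,
    NetworkValidationError,
    compile_step,
)

__all__ = [
    "DattaTable",
    "SizeCapError",
    "datta_solve",
    "datta_extract",
    "ComponentDP",
    "datta_component",
]


class SizeCapError(RuntimeError):
    """The explicit state table would exceed the configured size cap."""


@dataclass(frozen=True)
class DattaTable:
    """Backward reachability table: ``marked[t]`` holds the encoded states with D=1.

    States are encoded little-endian in declared internal-node order
    (``internal[i]`` contributes bit ``i``).
    """

    order: tuple[str, ...]
    marked: tuple[frozenset[int], ...]

    def reachable(self, state: Mapping[str, int], t: int) -> int:
        enc = sum(int(state[v]) << i for i, v in enumerate(self.order))
        return int(enc in self.marked[t])


def _encode(bits: Sequence[int]) -> int:
    return sum(b << i for i, b in enumerate(bits))


def datta_solve(
    problem: ControlProblem, *, max_nodes: int = 22, force: bool = False
) -> tuple[int, DattaTable]:
    """Full-network backward DP; returns (decision, filled table).

    Enumerates all ``2^n`` states and all ``2^m`` controls at every backward
    step, so it is the exponential baseline the SCC solver is measured
    against.  Refuses ``n > max_nodes`` unless ``force=True``.
    """
    net = problem.network
    if net.n > max_nodes and not force:
        raise SizeCapError(f"{net.n} internal nodes exceeds the cap of {max_nodes}")
    tau = problem.horizon
    step_fn = compile_step(net)
    n_states = 1 << net.n
    controls = list(itertools.product((0, 1), repeat=net.m))

    desired = problem.desired.as_tuple(net.internal)
    marked_tau = frozenset(
        s
        for s in range(n_states)
        if all(d is None or ((s >> i) & 1) == d for i, d in enumerate(desired))
    )
    marked: list[frozenset[int]] = [marked_tau]
    for _ in range(tau):
        nxt = marked[0]
        cur = set()
        for s in range(n_states):
            bits = tuple((s >> i) & 1 for i in range(net.n))
            for c in controls:
                if _encode(step_fn(bits, c)) in nxt:
                    cur.add(s)
                    break
        marked.insert(0, frozenset(cur))

    table = DattaTable(order=net.internal, marked=tuple(marked))
    init_enc = _encode([int(b) for b in problem.initial.as_tuple(net.internal)])
    return int(init_enc in table.marked[0]), table


def datta_extract(problem: ControlProblem, table: DattaTable) -> ControlSequence:
    """Forward walk on a filled table, picking the first marked successor per step."""
    net = problem.network
    step_fn = compile_step(net)
    bits = tuple(int(b) for b in problem.initial.as_tuple(net.internal))
    if _encode(bits) not in table.marked[0]:
        raise NetworkValidationError("problem is not solvable; nothing to extract")
    out = []
    for t in range(problem.horizon):
        for c in itertools.product((0, 1), repeat=net.m):
            nxt = step_fn(bits, c)
            if _encode(nxt) in table.marked[t + 1]:
                out.append({u: c[j] for j, u in enumerate(net.external)})
                bits = nxt
                break
        else:  # pragma: no cover - contradicts backward consistency
            raise AssertionError("inconsistent Datta table")
    return ControlSequence(assignments=tuple(out))


@dataclass(frozen=True)
class ComponentDP:
    """Per-component feasibility: forward-reachable ∩ backward-consistent states.

    ``feasible[t]`` holds encoded member states and ``edges[t]`` the
    admissible transitions between consecutive feasible layers; every edge is
    realized by at least one allowed input combination.
    """

    members: tuple[str, ...]
    feasible: tuple[frozenset[int], ...]
    edges: tuple[Mapping[int, frozenset[int]], ...]

    def gamma_entries(self) -> dict[tuple[str, int, int], bool]:
        """ϒ projection: (node, b, t) -> some feasible state at t has node = b."""
        out: dict[tuple[str, int, int], bool] = {}
        for t, layer in enumerate(self.feasible):
            for i, v in enumerate(self.members):
                seen = {(s >> i) & 1 for s in layer}
                out[(v, 0, t)] = 0 in seen
                out[(v, 1, t)] = 1 in seen
        return out

    def state_values(self, enc: int) -> dict[str, int]:
        return {v: (enc >> i) & 1 for i, v in enumerate(self.members)}


def datta_component(
    members: Sequence[str],
    network: BooleanNetwork,
    input_allowed: Mapping[str, Sequence[set[int]]],
    initial: Mapping[str, int],
    desired_at_tau: Mapping[str, int | None] | None,
    tau: int,
    *,
    max_members: int = 16,
) -> ComponentDP:
    """Backward DP for one component under per-time allowed input values.

    ``input_allowed`` maps every outside regulator of the component to a
    length ``τ+1`` list of allowed bit sets (time-indexed constants in the
    fully fixed case).  ``desired_at_tau`` restricts member values at the
    horizon (``None`` values, or ``None`` for the whole mapping, mean
    unconstrained).  Feasible layers are the intersection of forward
    reachability from ``initial`` with backward consistency toward the
    horizon restriction; an empty layer signals that the current upstream
    fixing cannot work and the caller must backtrack.
    """
    members = tuple(members)
    if len(members) > max_members:
        raise SizeCapError(f"component of {len(members)} nodes exceeds the cap of {max_members}")
    midx = {v: i for i, v in enumerate(members)}
    outside = []
    for v in members:
        for ref in network.inputs_of(v):
            if ref not in midx and ref not in outside:
                outside.append(ref)
    for x in outside:
        if x not in input_allowed:
            raise NetworkValidationError(f"missing allowed-value sets for upstream node {x!r}")

    funcs = [network.functions[v] for v in members]

    def transitions(enc: int, t: int) -> set[int]:
        base = {v: (enc >> i) & 1 for v, i in midx.items()}
        results = set()
        for combo in itertools.product(*(sorted(input_allowed[x][t]) for x in outside)):
            env = dict(base)
            env.update(zip(outside, combo))
            results.add(_encode([evaluate(f, env) for f in funcs]))
        return results

    n_states = 1 << len(members)
    # backward pass
    if desired_at_tau is None:
        back = set(range(n_states))
    else:
        back = {
            s
            for s in range(n_states)
            if all(
                desired_at_tau.get(v) is None or ((s >> i) & 1) == desired_at_tau[v]
                for v, i in midx.items()
            )
        }
    backward = [back]
    for t in range(tau - 1, -1, -1):
        backward.insert(
            0, {s for s in range(n_states) if transitions(s, t) & backward[0]}
        )
    # forward pass, intersected layer by layer; because each layer is both
    # reachable from the start and backward-consistent, every feasible state
    # automatically has an admissible predecessor and successor
    start = _encode([int(initial[v]) for v in members])
    feasible = [frozenset({start} & backward[0])]
    edges: list[dict[int, frozenset[int]]] = []
    for t in range(tau):
        layer_edges: dict[int, frozenset[int]] = {}
        nxt: set[int] = set()
        for s in feasible[t]:
            succ = transitions(s, t) & backward[t + 1]
            if succ:
                layer_edges[s] = frozenset(succ)
                nxt |= succ
        edges.append(layer_edges)
        feasible.append(frozenset(nxt))
    return ComponentDP(members=members, feasible=tuple(feasible), edges=tuple(edges))
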