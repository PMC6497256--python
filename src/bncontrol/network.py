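"""Core Boolean-network model and synchronous simulation semantics.

A network ``G = (V, F)`` has internal nodes ``v_1..v_n``, each with one
update function over AND/OR/NOT, and external (control) nodes ``u_1..u_m``
with no update function and no incoming edges.  All internal nodes update
synchronously from the time-``t`` values.  The control problem asks for a
sequence of external assignments ``u^0..u^{τ-1}`` driving the internal state
from ``v^0`` to the desired state at time ``τ`` (an assignment at time ``τ``
itself cannot influence ``v^τ`` and is not part of a solution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .expr import BoolExpr, evaluate, render, variables

__all__ = [
    "BooleanNetwork",
    "NetworkState",
    "ControlProblem",
    "ControlSequence",
    "NetworkValidationError",
    "step",
    "simulate",
    "verify_control",
    "compile_step",
]


class NetworkValidationError(ValueError):
    pass


@dataclass(frozen=True)
class BooleanNetwork:
    """Internal/external node lists plus one update expression per internal node.

    Node names are case-sensitive (the Drosophila model distinguishes ``wg``
    from ``WG``).  ``node_order`` — internal nodes in declared order followed
    by external nodes — fixes every state-vector and tie-breaking convention
    in the package.
    """

    internal: tuple[str, ...]
    external: tuple[str, ...]
    functions: Mapping[str, BoolExpr]

    def __post_init__(self):
        names = list(self.internal) + list(self.external)
        if len(set(names)) != len(names):
            raise NetworkValidationError("node names must be unique across internal and external")
        if not names:
            raise NetworkValidationError("network has no nodes")
        missing = [v for v in self.internal if v not in self.functions]
        if missing:
            raise NetworkValidationError(f"internal nodes without update function: {missing}")
        extra = set(self.functions) - set(self.internal)
        if extra:
            raise NetworkValidationError(
                f"update functions for non-internal nodes: {sorted(extra)}"
            )
        declared = set(names)
        for v in self.internal:
            for ref in variables(self.functions[v]):
                if ref not in declared:
                    raise NetworkValidationError(
                        f"update function of {v!r} references undeclared node {ref!r}"
                    )

    @property
    def node_order(self) -> tuple[str, ...]:
        return self.internal + self.external

    @property
    def n(self) -> int:
        return len(self.internal)

    @property
    def m(self) -> int:
        return len(self.external)

    def inputs_of(self, node: str) -> tuple[str, ...]:
        """Distinct regulators of an internal node (VAR occurrences in its function)."""
        return variables(self.functions[node])

    def describe(self) -> str:
        lines = [f"externals: {', '.join(self.external)}" if self.external else "externals:"]
        lines += [f"{v}, {render(self.functions[v])}" for v in self.internal]
        return "\n".join(lines)


@dataclass(frozen=True)
class NetworkState:
    """Values of all internal nodes at one time step.

    ``values`` maps node name -> bit; in a *desired* state ``None`` marks a
    don't-care node (unconstrained at the horizon).
    """

    time: int
    values: Mapping[str, int | None]

    def __post_init__(self):
        if self.time < 0:
            raise NetworkValidationError("time index must be >= 0")

    def bit(self, node: str) -> int | None:
        return self.values[node]

    def as_tuple(self, order: Sequence[str]) -> tuple[int | None, ...]:
        return tuple(self.values[v] for v in order)


def _check_total(state: NetworkState, network: BooleanNetwork, what: str, allow_dontcare: bool):
    for v in network.internal:
        if v not in state.values:
            raise NetworkValidationError(f"{what} state misses internal node {v!r}")
        b = state.values[v]
        if b is None:
            if not allow_dontcare:
                raise NetworkValidationError(f"{what} state has undetermined value for {v!r}")
        elif b not in (0, 1):
            raise NetworkValidationError(f"{what} state value for {v!r} is not a bit: {b!r}")
    extra = set(state.values) - set(network.internal)
    if extra:
        raise NetworkValidationError(f"{what} state assigns non-internal nodes: {sorted(extra)}")


@dataclass(frozen=True)
class ControlSequence:
    """Per-time external assignments ``u^0..u^{τ-1}`` (length = horizon)."""

    assignments: tuple[Mapping[str, int], ...]

    def __len__(self) -> int:
        return len(self.assignments)

    def bits(self, external_order: Sequence[str]) -> tuple[tuple[int, ...], ...]:
        return tuple(tuple(a[u] for u in external_order) for a in self.assignments)

    def switch_count(self) -> int:
        """Total adjacent-time value flips across external nodes within the sequence."""
        total = 0
        for prev, cur in zip(self.assignments, self.assignments[1:]):
            total += sum(1 for u in cur if cur[u] != prev[u])
        return total


@dataclass(frozen=True)
class ControlProblem:
    network: BooleanNetwork
    initial: NetworkState
    desired: NetworkState
    horizon: int

    def __post_init__(self):
        if self.horizon < 0:
            raise NetworkValidationError("horizon must be >= 0")
        _check_total(self.initial, self.network, "initial", allow_dontcare=False)
        _check_total(self.desired, self.network, "desired", allow_dontcare=True)

    def desired_matches(self, values: Mapping[str, int]) -> bool:
        return all(
            want is None or values[v] == want for v, want in self.desired.values.items()
        )


def step(
    network: BooleanNetwork,
    internal: NetworkState,
    external: Mapping[str, int],
) -> NetworkState:
    """One synchronous update: every internal node reads only time-``t`` values."""
    _check_total(internal, network, "current", allow_dontcare=False)
    for u in network.external:
        if u not in external:
            raise NetworkValidationError(f"external assignment misses node {u!r}")
    env = dict(internal.values)
    env.update({u: int(external[u]) for u in network.external})
    nxt = {v: evaluate(network.functions[v], env) for v in network.internal}
    return NetworkState(time=internal.time + 1, values=nxt)


def simulate(
    network: BooleanNetwork,
    initial: NetworkState,
    controls: ControlSequence,
) -> list[NetworkState]:
    """Iterate :func:`step`; returns the trajectory of length ``len(controls)+1``."""
    traj = [initial]
    for assignment in controls.assignments:
        traj.append(step(network, traj[-1], assignment))
    return traj


def verify_control(problem: ControlProblem, controls: ControlSequence) -> int:
    """1 iff simulating ``controls`` from the initial state meets the desired state at τ."""
    if len(controls) != problem.horizon:
        raise NetworkValidationError(
            f"control sequence length {len(controls)} != horizon {problem.horizon}"
        )
    final = simulate(problem.network, problem.initial, controls)[-1]
    return int(problem.desired_matches(dict(final.values)))


def compile_step(network: BooleanNetwork):
    """Compile the transition into ``f(state_tuple, control_tuple) -> state_tuple``.

    The returned function is semantically identical to :func:`step` on
    bit-tuples in ``internal``/``external`` declared order; it exists because
    the solvers evaluate millions of transitions.
    """
    from .expr import python_source

    refs = {v: f"s[{i}]" for i, v in enumerate(network.internal)}
    refs.update({u: f"c[{j}]" for j, u in enumerate(network.external)})
    body = ", ".join(python_source(network.functions[v], refs) for v in network.internal)
    comma = "," if network.n == 1 else ""
    src = f"def _step(s, c, FULL=1):\n    return ({body}{comma})\n"
    ns: dict = {}
    exec(src, ns)  # noqa: S102 - generated from validated ASTs only
    return ns["_step"]
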