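"""Seeded random-instance generator.

Real regulatory networks have small strongly connected components, which is
the regime the SCC solver is designed for; the generator therefore controls
the largest-SCC size directly (a planted cycle) on top of a sparse random
wiring.  Desired states are drawn from a simulated trajectory under random
controls with probability 1/2 — guaranteeing a healthy mix of solvable and
unsolvable instances — and uniformly at random otherwise.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .expr import And, BoolExpr, Const, Not, Or, Var
from .network import (
    BooleanNetwork,
    ControlProblem,
    ControlSequence,
    NetworkState,
    simulate,
)

__all__ = ["GeneratorSpec", "generate_random"]


@dataclass(frozen=True)
class GeneratorSpec:
    n_internal: int
    n_external: int = 1
    max_inputs_per_node: int = 3
    edge_density: float = 0.3
    target_largest_scc: int = 2
    horizon: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_internal < 1:
            raise ValueError("need at least one internal node")
        if self.n_external < 0:
            raise ValueError("negative external count")
        if not (0.0 <= self.edge_density <= 1.0):
            raise ValueError("edge_density must be in [0, 1]")
        if self.target_largest_scc > self.n_internal:
            raise ValueError("target_largest_scc exceeds the internal node count")
        if self.horizon < 0:
            raise ValueError("negative horizon")


def _random_expr(rng: random.Random, inputs: list[str]) -> BoolExpr:
    """Random AND/OR/NOT tree in which every listed input occurs at least once."""
    if not inputs:
        return Const(rng.randrange(2))
    terms: list[BoolExpr] = []
    for name in inputs:
        leaf: BoolExpr = Var(name)
        if rng.random() < 0.4:
            leaf = Not(leaf)
        terms.append(leaf)
    rng.shuffle(terms)
    while len(terms) > 1:
        k = min(len(terms), rng.randrange(2, 4))
        group, terms = tuple(terms[:k]), terms[k:]
        combined: BoolExpr = And(group) if rng.random() < 0.5 else Or(group)
        if rng.random() < 0.15:
            combined = Not(combined)
        terms.append(combined)
    return terms[0]


def generate_random(spec: GeneratorSpec) -> tuple[BooleanNetwork, ControlProblem, dict]:
    """Build a reproducible random instance; returns (network, problem, info).

    ``info`` reports the achieved SCC profile (``largest_scc``) and whether
    the desired state was planted on a reachable trajectory (``planted``).
    """
    rng = random.Random(spec.seed)
    internal = tuple(f"v{i+1}" for i in range(spec.n_internal))
    external = tuple(f"u{j+1}" for j in range(spec.n_external))

    inputs: dict[str, list[str]] = {v: [] for v in internal}
    # planted cycle fixes a lower bound on the largest SCC
    if spec.target_largest_scc >= 2:
        cycle = list(internal[: spec.target_largest_scc])
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            inputs[b].append(a)
    candidates = list(internal) + list(external)
    for v in internal:
        for j in candidates:
            if j in inputs[v] or len(inputs[v]) >= spec.max_inputs_per_node:
                continue
            if rng.random() < spec.edge_density:
                inputs[v].append(j)

    functions = {v: _random_expr(rng, inputs[v]) for v in internal}
    network = BooleanNetwork(internal=internal, external=external, functions=functions)

    initial = NetworkState(0, {v: rng.randrange(2) for v in internal})
    controls = ControlSequence(
        assignments=tuple(
            {u: rng.randrange(2) for u in external} for _ in range(spec.horizon)
        )
    )
    planted = rng.random() < 0.5
    if planted:
        desired_values = dict(simulate(network, initial, controls)[-1].values)
    else:
        desired_values = {v: rng.randrange(2) for v in internal}
    problem = ControlProblem(
        network=network,
        initial=initial,
        desired=NetworkState(spec.horizon, desired_values),
        horizon=spec.horizon,
    )

    import networkx as nx

    from .decompose import dependency_graph

    largest = max(
        (len(c) for c in nx.strongly_connected_components(dependency_graph(network))),
        default=1,
    )
    return network, problem, {"largest_scc": largest, "planted": planted}
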