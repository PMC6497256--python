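"""Dependency graph, SCC partition, component taxonomy, constant-node analysis.

The regulatory dependency graph has an edge ``j -> i`` exactly when node
``j`` appears in the update function of ``i`` (an occurrence counts even if
logically vacuous).  Its strongly connected components, in topological order
of the condensation, drive the solver: single-node components with at most
one outgoing edge are *simple non-branching*, single-node components feeding
two or more distinct consumers are *branching*, and components with two or
more members are *multi-node* and handled by per-component dynamic
programming.  A self-loop neither makes a single node multi-node (the
Drosophila model treats the self-dependent SLP and wg as single-node
components) nor counts as an outgoing edge for branching purposes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import networkx as nx

from .expr import Const, Var
from .network import BooleanNetwork, NetworkState

__all__ = [
    "Category",
    "Component",
    "dependency_graph",
    "strongly_connected_components",
    "classify_component",
    "weakly_connected_groups",
    "constant_profile",
    "frozen_nodes",
]


class Category(enum.Enum):
    SIMPLE_NONBRANCHING = "simple-nonbranching"
    BRANCHING_SINGLE = "branching-single"
    MULTI_NODE = "multi-node"


@dataclass(frozen=True)
class Component:
    """An SCC of the dependency graph with its topological index and category."""

    members: tuple[str, ...]  # sorted by declared node order
    topo_index: int
    category: Category
    out_degree: int  # condensation edges leaving the component

    @property
    def is_hard(self) -> bool:
        return self.category is not Category.SIMPLE_NONBRANCHING

    def __str__(self) -> str:
        return "{" + ", ".join(self.members) + "}"


def dependency_graph(network: BooleanNetwork) -> nx.DiGraph:
    """Directed graph with edge ``j -> i`` iff ``j`` occurs in ``f_i``."""
    g = nx.DiGraph()
    g.add_nodes_from(network.node_order)
    for v in network.internal:
        for ref in network.inputs_of(v):
            g.add_edge(ref, v)
    return g


def _node_index(network: BooleanNetwork) -> dict[str, int]:
    return {name: i for i, name in enumerate(network.node_order)}


def strongly_connected_components(
    graph: nx.DiGraph, network: BooleanNetwork
) -> list[Component]:
    """SCC partition in a deterministic topological order of the condensation.

    Among valid topological orders the one produced by Kahn's algorithm with
    a min-heap keyed by each component's smallest declared-node index is
    returned, so runs and golden tests are reproducible.
    """
    import heapq

    index = _node_index(network)
    sccs = [tuple(sorted(c, key=index.__getitem__)) for c in nx.strongly_connected_components(graph)]
    by_member = {m: i for i, scc in enumerate(sccs) for m in scc}

    cond_succ: list[set[int]] = [set() for _ in sccs]
    indeg = [0] * len(sccs)
    for a, b in graph.edges():
        ca, cb = by_member[a], by_member[b]
        if ca != cb and cb not in cond_succ[ca]:
            cond_succ[ca].add(cb)
            indeg[cb] += 1

    heap = [(index[sccs[i][0]], i) for i in range(len(sccs)) if indeg[i] == 0]
    heapq.heapify(heap)
    ordered: list[int] = []
    while heap:
        _, i = heapq.heappop(heap)
        ordered.append(i)
        for j in cond_succ[i]:
            indeg[j] -= 1
            if indeg[j] == 0:
                heapq.heappush(heap, (index[sccs[j][0]], j))

    components = []
    for topo, i in enumerate(ordered):
        members = sccs[i]
        category = _categorize(members, graph)
        components.append(
            Component(
                members=members,
                topo_index=topo,
                category=category,
                out_degree=len(cond_succ[i]),
            )
        )
    return components


def _categorize(members: tuple[str, ...], graph: nx.DiGraph) -> Category:
    if len(members) >= 2:
        return Category.MULTI_NODE
    node = members[0]
    # successors outside the node itself; a self-loop is not branching
    out = set(graph.successors(node)) - {node}
    return Category.BRANCHING_SINGLE if len(out) >= 2 else Category.SIMPLE_NONBRANCHING


def classify_component(
    component: Component, graph: nx.DiGraph, network: BooleanNetwork
) -> Category:
    """Category of an SCC (also stored on the component itself)."""
    return _categorize(component.members, graph)


def weakly_connected_groups(
    graph: nx.DiGraph, components: list[Component], network: BooleanNetwork
) -> list[list[Component]]:
    """Partition the component list into weakly connected groups.

    Nodes in different weak components of the dependency graph share no
    regulatory path in either direction, so their control subproblems are
    independent and are solved (and counted) separately.
    """
    index = _node_index(network)
    wcc = list(nx.weakly_connected_components(graph))
    by_member = {m: i for i, part in enumerate(wcc) for m in part}
    groups: dict[int, list[Component]] = {}
    for comp in components:
        groups.setdefault(by_member[comp.members[0]], []).append(comp)
    ordered = sorted(groups.values(), key=lambda comps: min(index[m] for c in comps for m in c.members))
    return [sorted(g, key=lambda c: c.topo_index) for g in ordered]


def constant_profile(
    network: BooleanNetwork, initial: NetworkState
) -> dict[str, tuple[int, int]]:
    """Nodes provably constant regardless of controls: name -> (bit, onset).

    ``onset`` is the first time step from which the node certainly holds
    ``bit`` for all later times: 0 for frozen-at-all-t nodes (constant
    functions agreeing with the initial state, input-free nodes, pure
    self-copies) and >= 1 for eventually-constant nodes such as Drosophila's
    ``en`` (en(t+1) = ¬SLP(t) = 1 once SLP is frozen at 0, although
    en(0) = 0).  Computed to fixpoint by partial evaluation: once every
    regulator a function still depends on is constant, the target is too.
    """
    from .expr import evaluate

    profile: dict[str, tuple[int, int]] = {}
    changed = True
    while changed:
        changed = False
        for v in network.internal:
            if v in profile:
                continue
            f = network.functions[v]
            deps = network.inputs_of(v)
            if isinstance(f, Var) and f.name == v:
                bit = int(initial.values[v])  # pure self-copy pins the initial value
                profile[v] = (bit, 0)
                changed = True
                continue
            known = {}
            onset = 0
            usable = True
            for d in deps:
                if d == v:
                    usable = False  # self-dependence beyond a pure copy: not handled
                    break
                if d in profile:
                    known[d] = profile[d][0]
                    onset = max(onset, profile[d][1])
                elif d in network.external:
                    usable = False
                    break
                else:
                    usable = False
                    break
            if not usable and deps:
                # partial evaluation may still force a constant (e.g. AND with a 0)
                bit = _partial_constant(f, {d: profile[d][0] for d in deps if d in profile})
                if bit is not None:
                    onset = max((profile[d][1] for d in deps if d in profile), default=0)
                    start = onset + 1
                    if start == 1 and int(initial.values[v]) == bit:
                        start = 0
                    profile[v] = (bit, start)
                    changed = True
                continue
            if not deps:
                bit = evaluate(f, {})
                start = 0 if int(initial.values[v]) == bit else 1
                profile[v] = (bit, start)
                changed = True
            elif usable:
                bit = evaluate(f, known)
                start = onset + 1
                if start == 1 and int(initial.values[v]) == bit:
                    start = 0
                profile[v] = (bit, start)
                changed = True
    return profile


def _partial_constant(expr, known: dict[str, int]) -> int | None:
    """Value of ``expr`` if forced by the known-constant inputs, else None."""
    from .expr import And, Not, Or

    match expr:
        case Const(value=v):
            return v
        case Var(name=name):
            return known.get(name)
        case Not(child=c):
            inner = _partial_constant(c, known)
            return None if inner is None else 1 - inner
        case And(children=cs):
            vals = [_partial_constant(c, known) for c in cs]
            if any(v == 0 for v in vals):
                return 0
            return 1 if all(v == 1 for v in vals) else None
        case Or(children=cs):
            vals = [_partial_constant(c, known) for c in cs]
            if any(v == 1 for v in vals):
                return 1
            return 0 if all(v == 0 for v in vals) else None
    return None


def frozen_nodes(network: BooleanNetwork, initial: NetworkState) -> set[tuple[str, int]]:
    """Nodes constant at *every* t (onset 0 in :func:`constant_profile`)."""
    return {
        (v, bit) for v, (bit, onset) in constant_profile(network, initial).items() if onset == 0
    }
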