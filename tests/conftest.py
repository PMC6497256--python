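"""Shared builders for test networks and naive reference computations."""

from __future__ import annotations

import itertools
import random

import pytest

from bncontrol import (
    BooleanNetwork,
    ControlProblem,
    ControlSequence,
    NetworkState,
    parse_expression,
    verify_control,
)
from bncontrol.expr import And, BoolExpr, Const, Not, Or, Var


def build_network(
    rules: dict[str, str], external: tuple[str, ...] = ()
) -> BooleanNetwork:
    return BooleanNetwork(
        internal=tuple(rules),
        external=external,
        functions={v: parse_expression(f) for v, f in rules.items()},
    )


def build_problem(
    net: BooleanNetwork,
    initial: dict[str, int],
    desired: dict[str, int | None],
    tau: int,
) -> ControlProblem:
    return ControlProblem(
        network=net,
        initial=NetworkState(0, initial),
        desired=NetworkState(tau, desired),
        horizon=tau,
    )


def all_control_sequences(net: BooleanNetwork, tau: int):
    """Every control sequence, by per-sequence construction (naive route)."""
    for bits in itertools.product((0, 1), repeat=net.m * tau):
        yield ControlSequence(
            assignments=tuple(
                {u: bits[t * net.m + j] for j, u in enumerate(net.external)}
                for t in range(tau)
            )
        )


def naive_decision(problem: ControlProblem) -> tuple[int, int]:
    """(decision, count) by simulating each sequence separately."""
    count = sum(
        verify_control(problem, cs)
        for cs in all_control_sequences(problem.network, problem.horizon)
    )
    return int(count > 0), count


def random_expression(rng: random.Random, names: list[str], depth: int) -> BoolExpr:
    if depth == 0 or rng.random() < 0.25:
        if rng.random() < 0.15:
            return Const(rng.randrange(2))
        return Var(rng.choice(names))
    kind = rng.randrange(3)
    if kind == 0:
        return Not(random_expression(rng, names, depth - 1))
    arity = rng.randrange(2, 4)
    children = tuple(random_expression(rng, names, depth - 1) for _ in range(arity))
    return And(children) if kind == 1 else Or(children)


@pytest.fixture
def drosophila():
    from bncontrol import drosophila_fixture

    return drosophila_fixture()


@pytest.fixture
def fig6():
    from bncontrol import fig6_fixture

    return fig6_fixture()
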