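"""Backward dynamic programming: full-network baseline and per-component engine."""

import itertools
import random

import pytest

from bncontrol import (
    ControlSequence,
    GeneratorSpec,
    brute_force_solve,
    datta_component,
    datta_extract,
    datta_solve,
    generate_random,
    verify_control,
)
from bncontrol.datta import SizeCapError

from conftest import build_network, build_problem


class TestFullNetworkDP:
    def test_horizon_layer_marks_exactly_the_desired_state(self):
        net = build_network({"a": "b | u", "b": "a"}, external=("u",))
        problem = build_problem(net, {"a": 0, "b": 0}, {"a": 1, "b": 0}, tau=3)
        _, table = datta_solve(problem)
        assert len(table.marked[3]) == 1
        assert table.reachable({"a": 1, "b": 0}, 3) == 1

    def test_toy_pair_reaches_10_at_three_steps(self, fig6):
        """The feedback pair with u free reaches (1,0) at τ=3 via u=(1,0,0)."""
        net = build_network(
            {"v1": "u | (!u & v2)", "v2": "!u & v1"}, external=("u",)
        )
        problem = build_problem(net, {"v1": 0, "v2": 0}, {"v1": 1, "v2": 0}, tau=3)
        decision, table = datta_solve(problem)
        assert decision == 1
        witness = datta_extract(problem, table)
        assert verify_control(problem, witness) == 1
        # the published trajectory's control u=(1,0,0) is among the solutions
        published = ControlSequence(tuple({"u": b} for b in (1, 0, 0)))
        assert verify_control(problem, published) == 1

    def test_decisions_match_brute_force_on_random_instances(self):
        """60 seeded instances (n<=6, m<=2, τ<=4): decision equals the oracle's."""
        for seed in range(60):
            spec = GeneratorSpec(
                n_internal=2 + seed % 5,
                n_external=seed % 3,
                edge_density=0.3,
                target_largest_scc=min(2, 2 + seed % 5),
                horizon=1 + seed % 4,
                seed=500 + seed,
            )
            _, problem, _ = generate_random(spec)
            oracle_decision, _, _ = brute_force_solve(problem)
            dp_decision, table = datta_solve(problem)
            assert dp_decision == oracle_decision
            if dp_decision:
                assert verify_control(problem, datta_extract(problem, table)) == 1

    def test_backward_self_consistency(self):
        """Every marked state before τ has a marked successor under some control."""
        from bncontrol.network import compile_step

        net = build_network({"a": "b & u", "b": "!a", "c": "a | b"}, external=("u",))
        problem = build_problem(
            net, {"a": 0, "b": 1, "c": 0}, {"a": 0, "b": 1, "c": 1}, tau=4
        )
        _, table = datta_solve(problem)
        step_fn = compile_step(net)
        for t in range(4):
            for enc in table.marked[t]:
                bits = tuple((enc >> i) & 1 for i in range(net.n))
                succs = {
                    sum(b << i for i, b in enumerate(step_fn(bits, (u,))))
                    for u in (0, 1)
                }
                assert succs & table.marked[t + 1]

    def test_size_cap_refuses_large_networks(self):
        rules = {f"n{i}": "0" for i in range(25)}
        net = build_network(rules)
        problem = build_problem(
            net, {v: 0 for v in rules}, {v: 0 for v in rules}, tau=1
        )
        with pytest.raises(SizeCapError):
            datta_solve(problem)


class TestComponentDP:
    def test_fixed_input_collapses_to_single_state_per_time(self, fig6):
        """With u fixed to (1,0,0,0) the pair has exactly one feasible state per t."""
        net, _ = fig6
        allowed = {"u": [{1}, {0}, {0}, {0}]}
        dp = datta_component(
            ("v1", "v2"), net, allowed, {"v1": 0, "v2": 0}, {"v1": 1, "v2": 0}, tau=3
        )
        assert all(len(layer) == 1 for layer in dp.feasible)
        gamma = dp.gamma_entries()
        expected_v1 = {0: (1, 0, 1, 0), 1: (0, 1, 0, 1)}
        expected_v2 = {0: (1, 1, 0, 1), 1: (0, 0, 1, 0)}
        for t in range(4):
            for b in (0, 1):
                assert gamma[("v1", b, t)] == bool(expected_v1[b][t])
                assert gamma[("v2", b, t)] == bool(expected_v2[b][t])

    def test_conflicting_horizon_restriction_empties_the_layers(self, fig6):
        # u held at 0 keeps the all-zero pair at zero; demanding (1,0) must fail
        net, _ = fig6
        allowed = {"u": [{0}] * 4}
        dp = datta_component(
            ("v1", "v2"), net, allowed, {"v1": 0, "v2": 0}, {"v1": 1, "v2": 0}, tau=3
        )
        assert all(len(layer) == 0 for layer in dp.feasible)

    def test_feasible_layers_match_explicit_trajectory_enumeration(self):
        """Random 3-node components vs. enumerate-all-trajectories-then-filter."""
        rng = random.Random(99)
        net = build_network(
            {"a": "b | x", "b": "c & !y", "c": "a & b"}, external=("x", "y")
        )
        for trial in range(25):
            tau = 3
            allowed = {
                x: [set(rng.choice([(0,), (1,), (0, 1)])) for _ in range(tau + 1)]
                for x in ("x", "y")
            }
            initial = {v: rng.randrange(2) for v in "abc"}
            desired = {v: rng.choice([0, 1, None]) for v in "abc"}
            dp = datta_component(("a", "b", "c"), net, allowed, initial, desired, tau)

            # oracle: enumerate every input trajectory explicitly
            from bncontrol import NetworkState, simulate
            from bncontrol.network import ControlSequence

            per_time_inputs = [
                list(itertools.product(sorted(allowed["x"][t]), sorted(allowed["y"][t])))
                for t in range(tau)
            ]
            reachable = [set() for _ in range(tau + 1)]
            for choice in itertools.product(*per_time_inputs):
                controls = ControlSequence(
                    tuple({"x": c[0], "y": c[1]} for c in choice)
                )
                traj = simulate(net, NetworkState(0, initial), controls)
                final = traj[-1].values
                if all(
                    desired[v] is None or final[v] == desired[v] for v in "abc"
                ):
                    for t, state in enumerate(traj):
                        enc = sum(
                            state.values[v] << i for i, v in enumerate(("a", "b", "c"))
                        )
                        reachable[t].add(enc)
            for t in range(tau + 1):
                assert dp.feasible[t] == reachable[t], (trial, t)
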