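"""The SCC-guided solver: golden ϒ tables, oracle equivalence, search behavior."""

import math

import pytest

from bncontrol import (
    ControlSequence,
    GeneratorSpec,
    NetworkState,
    brute_force_solve,
    datta_solve,
    dependency_graph,
    enumerate_component_sequences,
    fig6_problem,
    generate_random,
    minimize_switching,
    simulate,
    solve,
    strongly_connected_components,
    verify_control,
)
from bncontrol.solver import gamma_simple

from conftest import all_control_sequences, build_network, build_problem

# published ϒ table after fixing the control row (1,0,0,0): node -> b -> bits over t=0..3
PUBLISHED_GAMMA = {
    "u": {0: (0, 1, 1, 1), 1: (1, 0, 0, 0)},
    "v1": {0: (1, 0, 1, 0), 1: (0, 1, 0, 1)},
    "v2": {0: (1, 1, 0, 1), 1: (0, 0, 1, 0)},
    "v3": {0: (1, 1, 0, 1), 1: (0, 0, 1, 0)},
}


class TestGoldenToy:
    def test_external_state_space_order(self, fig6):
        """A free external over τ=3 yields 16 candidate rows; row #2 is (1,0,0,0)."""
        net, _ = fig6
        comps = strongly_connected_components(dependency_graph(net), net)
        space = enumerate_component_sequences(
            comps[0], net, {}, {v: 0 for v in net.internal}, {}, tau=3
        )
        assert len(space) == 16
        rows = [tuple(a["u"] for a in cand) for cand in space.candidates]
        assert rows[0] == (0, 0, 0, 0)
        assert rows[1] == (1, 0, 0, 0)
        assert rows[2] == (0, 1, 0, 0)
        assert len(set(rows)) == 16

    def test_solver_reproduces_published_gamma_cells(self):
        """Solving the toy problem fixes row #2 and matches both ϒ tables cell-for-cell."""
        problem = fig6_problem()
        result = solve(problem)
        assert result.solvable == 1 and result.verified == 1
        assert result.controls.bits(("u",)) == ((1,), (0,), (0,))
        for node, per_b in PUBLISHED_GAMMA.items():
            for b in (0, 1):
                for t in range(4):
                    assert result.gamma(node, b, t) == bool(per_b[b][t]), (node, b, t)

    def test_fixing_makes_gamma_single_valued(self):
        """After the search fixes every choice, each (node, t) has exactly one true bit."""
        result = solve(fig6_problem())
        for node in ("u", "v1", "v2", "v3"):
            for t in range(4):
                assert result.gamma(node, 0, t) != result.gamma(node, 1, t)

    def test_multi_node_component_has_single_candidate_under_fixing(self):
        result = solve(fig6_problem())
        assert result.stats.candidate_counts["{v1, v2}"] == 1


class TestGammaSimple:
    def test_or_node_existential_semantics(self):
        # ϒ1 of an OR node is true iff some input can be 1; ϒ0 iff both can be 0
        net = build_network({"a": "b | c", "b": "0", "c": "0"})
        allowed = {"b": [{0, 1}], "c": [{0}]}
        has0, has1 = gamma_simple("a", net, allowed, 0)
        assert (has0, has1) == (True, True)
        allowed = {"b": [{0}], "c": [{0}]}
        assert gamma_simple("a", net, allowed, 0) == (True, False)

    def test_and_node_requires_both_inputs(self):
        net = build_network({"a": "b & c", "b": "0", "c": "0"})
        allowed = {"b": [{0, 1}], "c": [{0}]}
        assert gamma_simple("a", net, allowed, 0) == (True, False)


class TestDrosophila:
    def test_solvable_at_horizon_six_with_verified_sequence(self, drosophila):
        _, problem = drosophila
        result = solve(problem)
        assert result.solvable == 1
        assert result.verified == 1
        assert verify_control(problem, result.controls) == 1

    def test_attainability_consistent_with_desired_state(self, drosophila):
        # if solvable, ϒ of the desired value is true at τ for every node
        _, problem = drosophila
        result = solve(problem)
        for v, want in problem.desired.values.items():
            assert result.gamma(v, want, problem.horizon)

    def test_extracted_sequence_has_six_steps(self, drosophila):
        _, problem = drosophila
        result = solve(problem)
        assert len(result.controls) == 6


class TestPitfall:
    def test_branching_dependency_is_not_oversold(self):
        """Per-node attainability is satisfiable but jointly contradictory: unsolvable.

        A branching node w = u feeds a = w and b = ¬w; demanding a = b = 1 at
        τ = 2 needs w(1) to be both 1 and 0.
        """
        net = build_network(
            {"w": "u", "a": "w", "b": "!w"}, external=("u",)
        )
        problem = build_problem(
            net, {"w": 0, "a": 0, "b": 0}, {"w": None, "a": 1, "b": 1}, tau=2
        )
        result = solve(problem)
        oracle, _, _ = brute_force_solve(problem)
        assert result.solvable == 0 and oracle == 0
        # each constraint alone is satisfiable
        for node, want in (("a", 1), ("b", 1)):
            relaxed = build_problem(
                net,
                {"w": 0, "a": 0, "b": 0},
                {"w": None, "a": None, "b": None} | {node: want},
                tau=2,
            )
            assert solve(relaxed).solvable == 1


class TestOracleEquivalence:
    def test_decisions_match_oracle_and_full_dp_on_random_suite(self):
        """200 seeded instances (n<=8, m<=2, τ<=5): all three methods agree."""
        solvable = 0
        for seed in range(200):
            spec = GeneratorSpec(
                n_internal=3 + seed % 6,
                n_external=seed % 3,
                max_inputs_per_node=3,
                edge_density=0.25 + 0.1 * (seed % 4),
                target_largest_scc=2 + seed % 2,
                horizon=1 + seed % 5,
                seed=seed,
            )
            _, problem, _ = generate_random(spec)
            oracle, witness, _ = brute_force_solve(problem)
            dp, _ = datta_solve(problem)
            result = solve(problem)
            assert result.solvable == dp == oracle, seed
            if result.solvable:
                solvable += 1
                assert result.verified == 1
                assert verify_control(problem, result.controls) == 1
                assert verify_control(problem, witness) == 1
        assert 0 < solvable < 200


class TestWorkSaving:
    @staticmethod
    def _chains(k: int, tau: int = 3):
        rules, external = {}, []
        for i in range(k):
            e = f"e{i}"
            external.append(e)
            rules[f"a{i}"] = e
            rules[f"b{i}"] = f"!{e}"
            rules[f"c{i}"] = f"a{i}"
        net = build_network(rules, external=tuple(external))
        init = NetworkState(0, {v: 0 for v in rules})
        # plant e = (0,1,0) so the search must reject candidates before success
        controls = ControlSequence(
            tuple({e: (1 if t == 1 else 0) for e in external} for t in range(tau))
        )
        final = simulate(net, init, controls)[-1]
        return build_problem(net, dict(init.values), dict(final.values), tau)

    def test_enumeration_adds_while_state_spaces_multiply(self):
        """k independent control chains: counter grows additively, product multiplicatively."""
        enumerated = {}
        products = {}
        for k in (1, 2, 3):
            result = solve(self._chains(k))
            assert result.solvable == 1
            enumerated[k] = result.stats.states_enumerated
            products[k] = math.prod(result.stats.candidate_counts.values())
        base = enumerated[1]
        assert base > 1  # the search really rejects candidates before succeeding
        assert enumerated[2] == 2 * base and enumerated[3] == 3 * base
        assert products[1] == 16 and products[2] == 16**2 and products[3] == 16**3


class TestEarlyRejection:
    def test_frozen_conflict_rejected_without_enumeration(self):
        net = build_network({"x": "x", "y": "u & x"}, external=("u",))
        problem = build_problem(net, {"x": 0, "y": 0}, {"x": 1, "y": 0}, tau=3)
        result = solve(problem)
        assert result.solvable == 0
        assert result.stats.states_enumerated == 0


class TestMinimalSwitching:
    def test_constant_solution_gives_zero_switches(self):
        net = build_network({"a": "u", "b": "a"}, external=("u",))
        problem = build_problem(net, {"a": 0, "b": 0}, {"a": 1, "b": 1}, tau=3)
        result = minimize_switching(problem)
        assert result.solvable == 1
        assert result.controls.switch_count() == 0

    def test_matches_exhaustive_minimum_on_random_instances(self):
        """Switch count equals the brute-force minimum over all valid sequences."""
        checked = 0
        for seed in range(40):
            spec = GeneratorSpec(
                n_internal=3 + seed % 4,
                n_external=1 + seed % 2,
                edge_density=0.3,
                target_largest_scc=2,
                horizon=2 + seed % 3,
                seed=1000 + seed,
            )
            _, problem, _ = generate_random(spec)
            best = None
            for cs in all_control_sequences(problem.network, problem.horizon):
                if verify_control(problem, cs):
                    sc = cs.switch_count()
                    best = sc if best is None else min(best, sc)
            result = minimize_switching(problem)
            if best is None:
                assert result.solvable == 0
            else:
                assert result.solvable == 1
                assert result.controls.switch_count() == best
                checked += 1
        assert checked > 5

    def test_drosophila_needs_at_most_two_switches(self, drosophila):
        # the U3 = (0,0,0,0,1,0) witness has two switches; the optimum is <= 2
        _, problem = drosophila
        result = minimize_switching(problem)
        assert result.solvable == 1
        assert result.controls.switch_count() <= 2
        assert verify_control(problem, result.controls) == 1


class TestEdgeCases:
    def test_zero_horizon(self):
        net = build_network({"a": "!a"})
        assert solve(build_problem(net, {"a": 1}, {"a": 1}, tau=0)).solvable == 1
        assert solve(build_problem(net, {"a": 1}, {"a": 0}, tau=0)).solvable == 0

    def test_uncontrolled_network_solvable_iff_trajectory_hits_desired(self):
        net = build_network({"a": "!a", "b": "a"})
        problem = build_problem(net, {"a": 0, "b": 0}, {"a": 1, "b": 0}, tau=3)
        # a alternates 0,1,0,1; b lags: at t=3 (a,b) = (1, 0)
        result = solve(problem)
        assert result.solvable == 1
        assert len(result.controls) == 3 and all(
            a == {} for a in result.controls.assignments
        )

    def test_dont_care_desired_nodes_relax_the_problem(self):
        net = build_network({"a": "u", "b": "!u"}, external=("u",))
        strict = build_problem(net, {"a": 0, "b": 0}, {"a": 1, "b": 1}, tau=1)
        relaxed = build_problem(net, {"a": 0, "b": 0}, {"a": 1, "b": None}, tau=1)
        assert solve(strict).solvable == 0
        assert solve(relaxed).solvable == 1
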