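"""Walk through the solver's machinery on the four-node didactic network.

One control u drives a two-node feedback pair (v1, v2); v3 copies v1 and
v4 = v2 AND v3.  The script prints the SCC decomposition, the 16-row state
space of the free control over τ=3, and the per-node/per-time attainability
(ϒ) table after the search fixes its choices — the solver's internal view
of which values each node can still take at each step.
"""

from bncontrol import (
    dependency_graph,
    enumerate_component_sequences,
    fig6_fixture,
    fig6_problem,
    solve,
    strongly_connected_components,
)

network, initial = fig6_fixture()
problem = fig6_problem()

print("components in topological order:")
comps = strongly_connected_components(dependency_graph(network), network)
for c in comps:
    print(f"  #{c.topo_index}  {{{', '.join(c.members)}}}  {c.category.value}")

space = enumerate_component_sequences(
    comps[0], network, {}, {v: 0 for v in network.internal}, {}, tau=3
)
print(f"\nstate space of the free control u over t=0..3: {len(space)} rows")
for k, cand in enumerate(space.candidates[:4], start=1):
    print(f"  row #{k}: {tuple(a['u'] for a in cand)}")
print("  ... (binary counting, t=0 least significant)")

result = solve(problem)
print(f"\nsolvable: {result.solvable}; extracted u sequence: "
      f"{tuple(a['u'] for a in result.controls.assignments)}")
print("ϒ table after the search fixed row #2 (1 = value attainable):")
print("node b | t=0 t=1 t=2 t=3")
for node in ("u", "v1", "v2", "v3", "v4"):
    for b in (0, 1):
        bits = "   ".join(str(int(result.gamma(node, b, t))) for t in range(4))
        print(f"{node:4} {b} |  {bits}")
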