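"""Find a valid control strategy with the fewest on/off switches.

Among all control sequences that solve the Drosophila instance, the variant
below minimizes the number of adjacent-time value flips summed over the
control nodes — fewer switches means a simpler intervention protocol.
"""

from bncontrol import drosophila_fixture, minimize_switching, solve

network, problem = drosophila_fixture()

plain = solve(problem)
best = minimize_switching(problem)

print("any valid sequence   :", plain.controls.bits(network.external),
      "switches =", plain.controls.switch_count())
print("minimum-switch one   :", best.controls.bits(network.external),
      "switches =", best.controls.switch_count())
print("\nboth sequences are verified by forward simulation; the second is the")
print("optimum over every valid sequence (ties broken lexicographically).")
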