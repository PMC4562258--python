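"""Finding the attractors the trap spaces miss.

When completeness fails, the counterexample state of the refuted
reachability query cannot reach any minimal trap space — so every attractor
reachable from it lies outside the approximation.  A verified random walk
from the counterexample produces one representative state per missed
attractor.
"""

from booltrap import attractors_oracle, minimal_trap_spaces, outside_attractors
from booltrap.fixtures import fixture

net = fixture("incomplete3")
print("minimal trap spaces:", list(minimal_trap_spaces(net)))
reps = outside_attractors(net, seed=1)
print("representatives of attractors outside them:", reps)

print("\ncross-check against the explicit attractor oracle:")
for a in attractors_oracle(net):
    mark = "<- contains the representative" if any(r in a for r in reps) else ""
    print("  attractor", sorted(a), mark)
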