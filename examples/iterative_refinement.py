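"""Deciding completeness without the full state space.

The refinement algorithm works on restrictions to autonomous sets (variable
sets containing all their own regulators) of each working trap space.  For
the six-variable model it model checks two 4-state systems instead of one
64-state system; for the cascade model the first autonomous set is
trap-space-free and must be extended downward to the next feedback
component.
"""

from booltrap import is_complete_iterative
from booltrap.fixtures import fixture

for name in ("coupled6", "cascade3"):
    net = fixture(name)
    verdict, trace = is_complete_iterative(net)
    print(f"{name}: complete = {verdict.holds}")
    for step in trace.steps:
        print(f"  pop {step.popped!r} -> {step.outcome}")
        for check in step.checks:
            status = ("trap-space-free" if check.complete is None
                      else f"complete={check.complete}")
            print(f"    checked restriction {check.variables} "
                  f"(traps {check.min_trap_spaces}): {status}")
        if step.pushed:
            print(f"    pushed {step.pushed}")
        if step.confirmed:
            print(f"    confirmed minimal {step.confirmed}")
    print()

print("every model-checked system above is a strict subnetwork: the full "
      "transition graph is never built.")
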