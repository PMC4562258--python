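"""Grading an approximation: faithfulness, univocality, completeness.

Three small networks show the three independent failure modes.  A perfect
approximation (faithful + univocal + complete) means the minimal trap
spaces correspond one-to-one to the asynchronous attractors with exactly
matching oscillating dimensions.
"""

from booltrap import analyze
from booltrap.fixtures import fixture

for name in ("coupled6", "incomplete3", "unfaithful3"):
    report = analyze(fixture(name), seed=0)
    print(f"{name}: minimal trap spaces = {report.minimal_trap_spaces}")
    for t in report.trap_spaces:
        kind = "steady" if t.steady else "cyclic"
        print(f"  {t.trap_space} ({kind}): univocal={t.univocal} "
              f"faithful={t.faithful} attractor state={t.attractor_state}")
    print(f"  complete={report.complete} -> perfect={report.perfect}")
    if report.outside_attractors:
        print(f"  attractor(s) outside the trap spaces, e.g. "
              f"{report.outside_attractors[0]}")
    print()

print("coupled6 is perfect; incomplete3 misses a cyclic attractor "
      "(completeness fails); unfaithful3 has a free dimension that never "
      "oscillates (faithfulness fails).")
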