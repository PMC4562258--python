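"""Built-in example networks.

Six small networks with pinned behaviour, used throughout the tests and the
example scripts:

* ``incomplete3`` — three variables whose minimal trap spaces {111, -00}
  miss a cyclic attractor: the approximation is not complete.
* ``inputs4`` — two self-sustaining inputs driving a two-variable cascade;
  the four input combinations percolate exactly onto the minimal trap
  spaces, so the approximation is complete.
* ``coupled6`` — two independent positive feedback loops feeding a negative
  loop; a perfect approximation with three steady states and one cyclic
  trap space, and the showcase for intersecting complete sets.
* ``xnor2`` — both variables compute XNOR; two attractors (a fixed point
  and a 3-cycle) in the trap-space-free plane, so ε is not univocal.
* ``cascade3`` — a negative two-loop driving a self-sustaining output; the
  minimal autonomous set is trap-space-free and must be extended.
* ``unfaithful3`` — a NOR pair with an AND readout; trap-space-free with a
  unique attractor whose third variable never oscillates, so ε is complete
  and univocal but not faithful.
"""

from __future__ import annotations

from .network import BooleanNetwork, parse_network

SOURCES: dict[str, str] = {
    "incomplete3": """\
v1, !v1&!v2 | v1&v2 | v2&!v3
v2, !v1&!v2&v3 | v1&v2&v3
v3, v2 | v3
""",
    "inputs4": """\
v1, v1
v2, v2
v3, v1 & !v4
v4, v2 & v3
""",
    "coupled6": """\
v1, v2
v2, v1
v3, v4
v4, v3
v5, v2 & !v6
v6, v3 & v5
""",
    "xnor2": """\
v1, !v1&!v2 | v1&v2
v2, !v1&!v2 | v1&v2
""",
    "cascade3": """\
v1, !v2
v2, v1
v3, v1 | v3
""",
    "unfaithful3": """\
v1, !v1 & !v2
v2, !v1 & !v2
v3, v1 & v2
""",
}


def builtin_fixtures() -> dict[str, BooleanNetwork]:
    """Parse and return all built-in fixture networks by name."""
    return {name: parse_network(src) for name, src in SOURCES.items()}


def fixture(name: str) -> BooleanNetwork:
    try:
        return parse_network(SOURCES[name])
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(SOURCES)}"
        ) from None
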