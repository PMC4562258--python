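"""Boolean networks, states and subspaces.

A network is a pair (V, F): an ordered tuple of variable names and one update
function per variable.  The declaration order is total and stable — it defines
the positions of the bit-string codecs used throughout the package, so a state
of a 3-variable network is written ``"110"`` (first variable = 1, second = 1,
third = 0) and a subspace with a free third variable is written ``"11-"``.
``'*'`` and ``'⋆'`` are accepted as input aliases for ``'-'``.

Subspaces are the central geometric object: a subspace ``p`` fixes a subset
``D_p`` of the variables and references the ``2^(n - |D_p|)`` states that
agree with it.  A *trap space* is a subspace the dynamics cannot leave, which
holds — independently of the update rule — exactly when every fixed
variable's function restricted to the subspace is constantly its fixed value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

from .expressions import (
    NAME_RE,
    BnetSyntaxError,
    Expression,
    depends_on,
    format_expression,
    parse_expression,
)

#: A state or subspace given either in bit-string codec or as a dict.
SubspaceLike = Union[str, Mapping[str, int]]

FREE_CHARS = {"-", "*", "⋆"}


@dataclass(frozen=True)
class BooleanNetwork:
    """A Boolean network (V, F) with a fixed variable order."""

    variables: tuple[str, ...]
    functions: dict[str, Expression] = field(compare=True)

    def __post_init__(self):
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable declaration")
        declared = set(self.variables)
        if set(self.functions) != declared:
            raise ValueError("every variable must have exactly one update function")
        for v in self.variables:
            undeclared = self.functions[v].variables() - declared
            if undeclared:
                raise ValueError(
                    f"function of {v!r} references undeclared variable(s) "
                    f"{sorted(undeclared)}"
                )

    # -- basic protocol -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BooleanNetwork)
            and other.variables == self.variables
            and other.functions == self.functions
        )

    def __hash__(self) -> int:
        return hash((self.variables, tuple(self.functions[v] for v in self.variables)))

    def __repr__(self) -> str:
        return f"BooleanNetwork(n={self.n}, variables={list(self.variables)})"

    # -- codecs -------------------------------------------------------------

    def subspace(self, p: SubspaceLike) -> dict[str, int]:
        """Normalize a subspace given as codec string or dict to a dict."""
        if isinstance(p, str):
            if len(p) != self.n:
                raise ValueError(
                    f"subspace string {p!r} has length {len(p)}, expected {self.n}"
                )
            out = {}
            for v, c in zip(self.variables, p):
                if c in FREE_CHARS:
                    continue
                if c not in "01":
                    raise ValueError(f"invalid subspace character {c!r} in {p!r}")
                out[v] = int(c)
            return out
        unknown = set(p) - set(self.variables)
        if unknown:
            raise ValueError(f"subspace fixes unknown variable(s) {sorted(unknown)}")
        return {v: int(p[v]) for v in self.variables if v in p}

    def state(self, x: SubspaceLike) -> dict[str, int]:
        """Normalize a full state; every variable must be fixed."""
        s = self.subspace(x)
        if len(s) != self.n:
            missing = [v for v in self.variables if v not in s]
            raise ValueError(f"state leaves variable(s) {missing} unassigned")
        return s

    def format(self, p: SubspaceLike) -> str:
        """Render a state/subspace in bit-string codec ('-' marks free)."""
        d = self.subspace(p)
        return "".join(str(d[v]) if v in d else "-" for v in self.variables)

    def states(self, p: SubspaceLike = "") -> Iterable[str]:
        """Iterate the referenced states S[p] in lexicographic codec order."""
        d = self.subspace(p) if p != "" else {}
        free = [v for v in self.variables if v not in d]
        for bits in itertools.product("01", repeat=len(free)):
            full = dict(d)
            full.update({v: int(b) for v, b in zip(free, bits)})
            yield self.format(full)

    # -- semantics ----------------------------------------------------------

    def evaluate(self, v: str, x: SubspaceLike) -> int:
        """Evaluate f_v at state x."""
        return self.functions[v].evaluate(self.state(x))

    def image(self, x: SubspaceLike) -> str:
        """The image F(x): componentwise evaluation of all update functions."""
        s = self.state(x)
        return "".join(str(self.functions[v].evaluate(s)) for v in self.variables)

    def to_bnet(self, header: bool = False) -> str:
        lines = ["targets, factors"] if header else []
        for v in self.variables:
            lines.append(f"{v}, {format_expression(self.functions[v])}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# parsing / writing the .bnet dialect


def parse_network(text: str) -> BooleanNetwork:
    """Parse BoolNet-style source: one ``name, expression`` line per variable.

    An optional ``targets, factors`` header and ``#`` comments are allowed.
    Declaration order defines the bit-string positions.  Undeclared
    references, duplicate declarations and syntax errors are reported with
    their line number.
    """
    variables: list[str] = []
    functions: dict[str, Expression] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "," not in line:
            raise BnetSyntaxError("expected 'name, expression'", lineno)
        name, _, rhs = line.partition(",")
        name = name.strip()
        if not variables and name == "targets" and rhs.strip() == "factors":
            continue  # header line
        if not NAME_RE.fullmatch(name):
            raise BnetSyntaxError(f"invalid variable name {name!r}", lineno)
        if name in functions:
            raise BnetSyntaxError(f"duplicate declaration of {name!r}", lineno)
        variables.append(name)
        functions[name] = parse_expression(rhs, line=lineno)
    if not variables:
        raise BnetSyntaxError("no variable declarations found")
    declared = set(variables)
    for lineno, v in enumerate(variables, start=1):
        undeclared = functions[v].variables() - declared
        if undeclared:
            raise BnetSyntaxError(
                f"function of {v!r} references undeclared variable(s) "
                f"{sorted(undeclared)}"
            )
    return BooleanNetwork(tuple(variables), functions)


# ---------------------------------------------------------------------------
# reduction, restriction, percolation


def substitute(net: BooleanNetwork, p: SubspaceLike) -> BooleanNetwork:
    """The network over the free variables of ``p`` with values substituted.

    For a trap space ``p`` this is the reduced network (V_p, F_p), which fully
    specifies the dynamics inside S[p].  Plain substitution is allowed for
    any subspace; the reduced-network reading is the caller's obligation.
    """
    d = net.subspace(p)
    keep = tuple(v for v in net.variables if v not in d)
    functions = {v: net.functions[v].substitute(d) for v in keep}
    return BooleanNetwork(keep, functions)


def restrict(net: BooleanNetwork, U: Iterable[str]) -> BooleanNetwork:
    """The restricted network (U, F|U) of an autonomous variable set U.

    Autonomy is checked semantically: a function of U may mention an outside
    variable syntactically as long as it does not depend on it (the
    ineffective reference is then substituted away).  Raises ``ValueError``
    if some function of U genuinely depends on a variable outside U.
    """
    keep = set(U)
    unknown = keep - set(net.variables)
    if unknown:
        raise ValueError(f"unknown variable(s) {sorted(unknown)}")
    order = tuple(v for v in net.variables if v in keep)
    functions = {}
    for v in order:
        f = net.functions[v]
        outside = f.variables() - keep
        if outside:
            for u in sorted(outside):
                if depends_on(f, u):
                    raise ValueError(
                        f"{sorted(keep)} is not autonomous: f_{v} depends on {u!r}"
                    )
            f = f.substitute({u: 0 for u in outside})
        functions[v] = f
    return BooleanNetwork(order, functions)


def is_trap_space(net: BooleanNetwork, p: SubspaceLike) -> bool:
    """Whether ``p`` is a trap space: each fixed variable's substituted
    function is semantically constant at its fixed value.

    Update-rule independent.
    """
    d = net.subspace(p)
    return all(net.functions[v].constancy(d) == c for v, c in d.items())


def percolate(net: BooleanNetwork, p: SubspaceLike) -> str:
    """The percolation p→ of a trap space: iteratively fix every variable
    whose substituted function has become constant, until stable.

    The result is a trap space ≤ p; percolation is monotone and idempotent.
    Raises ``ValueError`` if ``p`` is not a trap space (attractor containment
    inside the percolation is only guaranteed for trap spaces).
    """
    d = net.subspace(p)
    if not is_trap_space(net, d):
        raise ValueError(f"{net.format(d)!r} is not a trap space")
    current = dict(d)
    while True:
        new = dict(current)
        for v in net.variables:
            c = net.functions[v].constancy(current)
            if c is not None:
                new[v] = c
        if new == current:
            return net.format(current)
        current = new


def constants_preprocess(net: BooleanNetwork) -> tuple[str, BooleanNetwork]:
    """Percolate the constants subspace and strip it off.

    Returns ``(p, reduced)`` where ``p`` is the percolated subspace of
    iteratively forced variables (over the full variable order) and
    ``reduced`` is the constant-free network over the remaining variables.
    Attractors of ``net`` and ``reduced`` correspond one-to-one.  A network
    that percolates to a single state returns that state and an empty
    network.
    """
    seed = {}
    for v in net.variables:
        c = net.functions[v].constancy()
        if c is not None:
            seed[v] = c
    p = percolate(net, seed)
    return p, substitute(net, p)


def steady_states(net: BooleanNetwork) -> list[str]:
    """All fixed points of F, i.e. solutions of F(x) = x.

    Identical under the synchronous and asynchronous rules.  Solved by a
    depth-first search with constancy propagation rather than full state
    enumeration.
    """
    results: list[str] = []

    def search(partial: dict[str, int]) -> None:
        # propagate forced values; die on contradiction
        partial = dict(partial)
        while True:
            changed = False
            for v in net.variables:
                c = net.functions[v].constancy(partial)
                if c is None:
                    continue
                if v in partial:
                    if partial[v] != c:
                        return
                else:
                    partial[v] = c
                    changed = True
            if not changed:
                break
        todo = [v for v in net.variables if v not in partial]
        if not todo:
            # all functions constant-consistent: verify closure caught all
            results.append(net.format(partial))
            return
        u = todo[0]
        for bit in (0, 1):
            search({**partial, u: bit})

    search({})
    return sorted(set(results))


# ---------------------------------------------------------------------------
# subspace lattice operations


def subspace_leq(net: BooleanNetwork, p: SubspaceLike, q: SubspaceLike) -> bool:
    """p ≤ q iff S[p] ⊆ S[q]: q's fixings are a consistent subset of p's."""
    dp, dq = net.subspace(p), net.subspace(q)
    return all(v in dp and dp[v] == c for v, c in dq.items())


def subspace_consistent(net: BooleanNetwork, p: SubspaceLike, q: SubspaceLike) -> bool:
    dp, dq = net.subspace(p), net.subspace(q)
    return all(dp[v] == dq[v] for v in dp.keys() & dq.keys())


def subspace_intersect(net: BooleanNetwork, p: SubspaceLike, q: SubspaceLike) -> str:
    """The intersection z = p ⊓ q with S[z] = S[p] ∩ S[q].

    Raises ``ValueError`` on inconsistent subspaces.
    """
    dp, dq = net.subspace(p), net.subspace(q)
    for v in dp.keys() & dq.keys():
        if dp[v] != dq[v]:
            raise ValueError(
                f"subspaces {net.format(dp)!r} and {net.format(dq)!r} are inconsistent"
            )
    return net.format({**dp, **dq})


def lift_subspace(net: BooleanNetwork, sub: BooleanNetwork, q: SubspaceLike) -> str:
    """Lift a subspace of a sub-network (reduction/restriction) to ``net``."""
    d = sub.subspace(q)
    return net.format(d)
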