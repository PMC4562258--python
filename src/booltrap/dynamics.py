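"""Explicit-state dynamics and a native checker for a CTL fragment.

The asynchronous rule moves one variable per transition toward its update
function's value; fixed points carry a self-loop, so every state has at
least one successor and all infinite-path CTL semantics are well defined.
The synchronous rule is deterministic: x ↠ F(x).

The CTL fragment has atoms ``v = c`` and ``δ_v = d`` (δ_v(x) = f_v(x) − x(v),
i.e. whether v is increasing, steady or decreasing at x), their negations,
conjunction, disjunction, EF ("exists finally") and AG ("always globally").
Satisfaction sets are computed by backward fixpoints on the explicit
transition graph: Sat(EF φ) is the backward closure of Sat(φ) under the
predecessor relation, and Sat(AG φ) is the complement of the backward
closure of the complement of Sat(φ) — sound here because complementation is
applied to computed state sets, never to formulas.

Attractors are the terminal SCCs of the transition graph; an explicit
enumeration of them serves as the ground-truth oracle in tests.  The
intended use of this module is on *reduced or restricted* networks: the
refinement algorithm exists precisely to keep the checked systems small.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Union

import networkx as nx

from .expressions import Expression, format_expression
from .network import BooleanNetwork, SubspaceLike, is_trap_space

__all__ = [
    "StateCapExceeded",
    "TransitionSystem",
    "successors_async",
    "successors_sync",
    "build_ts",
    "attractors_oracle",
    "random_walk",
    "Atom",
    "And",
    "Or",
    "EF",
    "AG",
    "TRUE",
    "CTLFormula",
    "subspace_formula",
    "sat_set",
    "ctl_check",
    "Verdict",
    "to_smv",
]

DEFAULT_STATE_CAP = 25  # maximum number of variables for explicit systems


class StateCapExceeded(ValueError):
    """An explicit transition system would exceed the variable cap."""


# ---------------------------------------------------------------------------
# bit-level compilation


def _compile_functions(net: BooleanNetwork):
    """Compile every update function to a callable over integer state codes.

    State codes treat the first declared variable as the most significant
    bit, matching the bit-string codec (``int(s, 2)``).
    """
    n = net.n
    shift = {v: n - 1 - i for i, v in enumerate(net.variables)}

    def bitref(name: str) -> str:
        return f"((x >> {shift[name]}) & 1)"

    funcs = []
    for v in net.variables:
        src = net.functions[v].to_python(bitref)
        funcs.append(eval(f"lambda x: 1 if {src} else 0", {}))  # noqa: S307
    return funcs


class TransitionSystem:
    """An explicit transition system over all states of a network.

    States are integer codes; the codec string of code ``x`` is its binary
    rendering in declared variable order.  Total by construction.
    """

    def __init__(self, net: BooleanNetwork, rule: str = "async",
                 init: Union[str, SubspaceLike, Iterable[SubspaceLike]] = "all",
                 cap: int = DEFAULT_STATE_CAP):
        if rule not in ("async", "sync"):
            raise ValueError(f"unknown update rule {rule!r}")
        if net.n > cap:
            raise StateCapExceeded(
                f"network has {net.n} variables, explicit-state cap is {cap}"
            )
        self.net = net
        self.rule = rule
        self.n = net.n
        self.size = 1 << net.n
        self._funcs = _compile_functions(net)
        self.init = frozenset(self._parse_init(init))
        self._succ: Optional[list[tuple[int, ...]]] = None
        self._pred: Optional[list[list[int]]] = None

    # -- codecs -------------------------------------------------------------

    def encode(self, x: SubspaceLike) -> int:
        return int(self.net.format(self.net.state(x)) or "0", 2)

    def decode(self, code: int) -> str:
        return format(code, f"0{self.n}b") if self.n else ""

    def _parse_init(self, init) -> Iterable[int]:
        if isinstance(init, str) and init == "all":
            return range(self.size)
        if isinstance(init, (str, dict)):
            sub = self.net.subspace(init)
            return (self.encode(s) for s in self.net.states(sub))
        return (self.encode(x) for x in init)

    # -- transitions --------------------------------------------------------

    def image_code(self, x: int) -> int:
        y = 0
        for f in self._funcs:
            y = (y << 1) | f(x)
        return y

    def successors_of(self, x: int) -> tuple[int, ...]:
        if self.rule == "sync":
            return (self.image_code(x),)
        y = self.image_code(x)
        if y == x:
            return (x,)
        diff = x ^ y
        out = []
        for i in range(self.n):
            bit = 1 << (self.n - 1 - i)
            if diff & bit:
                out.append(x ^ bit)
        return tuple(out)

    @property
    def successors(self) -> list[tuple[int, ...]]:
        if self._succ is None:
            self._succ = [self.successors_of(x) for x in range(self.size)]
            assert all(self._succ)  # totality
        return self._succ

    @property
    def predecessors(self) -> list[list[int]]:
        if self._pred is None:
            pred: list[list[int]] = [[] for _ in range(self.size)]
            for x, succs in enumerate(self.successors):
                for y in succs:
                    pred[y].append(x)
            self._pred = pred
        return self._pred

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.size))
        for x, succs in enumerate(self.successors):
            g.add_edges_from((x, y) for y in succs)
        return g

    # -- atom labels --------------------------------------------------------

    def _index(self, v: str) -> int:
        try:
            return self.net.variables.index(v)
        except ValueError:
            raise ValueError(f"atom references unknown variable {v!r}") from None

    def label_var(self, x: int, v: str) -> int:
        return (x >> (self.n - 1 - self._index(v))) & 1

    def label_delta(self, x: int, v: str) -> int:
        i = self._index(v)
        return self._funcs[i](x) - self.label_var(x, v)


def successors_async(net: BooleanNetwork, x: SubspaceLike) -> set[str]:
    """Asynchronous successors: the self-loop at a fixed point, otherwise the
    states obtained by flipping exactly one disagreeing variable."""
    s = net.state(x)
    y = net.image(s)
    cur = net.format(s)
    if y == cur:
        return {cur}
    return {
        cur[:i] + y[i] + cur[i + 1:]
        for i in range(net.n)
        if cur[i] != y[i]
    }


def successors_sync(net: BooleanNetwork, x: SubspaceLike) -> set[str]:
    """Synchronous successor: the singleton {F(x)}."""
    return {net.image(x)}


def build_ts(net: BooleanNetwork, rule: str = "async",
             init="all", cap: int = DEFAULT_STATE_CAP) -> TransitionSystem:
    """Materialize the explicit transition system of a network.

    ``init`` is ``"all"``, a subspace (codec string or dict) or an iterable
    of states.  Raises :class:`StateCapExceeded` above ``cap`` variables.
    """
    return TransitionSystem(net, rule, init, cap)


def attractors_oracle(net: BooleanNetwork, rule: str = "async",
                      cap: int = DEFAULT_STATE_CAP) -> list[frozenset[str]]:
    """All attractors as explicit state sets: the terminal SCCs of the STG.

    Ground truth for tests; exponential in n by construction.
    """
    ts = build_ts(net, rule, "all", cap)
    g = ts.graph()
    cond = nx.condensation(g)
    out = []
    for comp_id in cond.nodes:
        if cond.out_degree(comp_id) == 0:
            members = cond.nodes[comp_id]["members"]
            out.append(frozenset(ts.decode(x) for x in members))
    return sorted(out, key=lambda a: sorted(a))


def random_walk(net: BooleanNetwork, p: SubspaceLike, seed: int,
                k: Optional[int] = None) -> str:
    """A seeded asynchronous random walk inside a trap space.

    Starts at a uniform random state of S[p], takes ``k`` uniform successor
    steps (default 10·|V_p|, enough in practice to reach an attractor) and
    returns the final state.  Deterministic for a fixed seed.
    """
    d = net.subspace(p)
    if not is_trap_space(net, d):
        raise ValueError(f"{net.format(d)!r} is not a trap space")
    rng = random.Random(seed)
    if k is None:
        k = 10 * (net.n - len(d))
    state = dict(d)
    for v in net.variables:
        if v not in state:
            state[v] = rng.randint(0, 1)
    cur = net.format(state)
    for _ in range(k):
        succs = sorted(successors_async(net, cur))
        cur = succs[rng.randrange(len(succs))]
    return cur


# ---------------------------------------------------------------------------
# CTL fragment


@dataclass(frozen=True)
class Atom:
    """An atomic proposition ``v = value`` (kind="var") or ``δ_v = value``
    (kind="delta"), optionally negated (the ≠ operator)."""

    kind: str  # "var" | "delta"
    var: str
    value: int
    negated: bool = False

    def __post_init__(self):
        if self.kind not in ("var", "delta"):
            raise ValueError(f"unknown atom kind {self.kind!r}")
        allowed = (0, 1) if self.kind == "var" else (-1, 0, 1)
        if self.value not in allowed:
            raise ValueError(f"invalid {self.kind} atom value {self.value!r}")

    def __str__(self):
        op = "!=" if self.negated else "="
        name = self.var if self.kind == "var" else f"delta({self.var})"
        return f"{name}{op}{self.value}"


@dataclass(frozen=True)
class And:
    args: tuple

    def __str__(self):
        return "(" + " & ".join(map(str, self.args)) + ")" if self.args else "true"


@dataclass(frozen=True)
class Or:
    args: tuple

    def __str__(self):
        return "(" + " | ".join(map(str, self.args)) + ")" if self.args else "false"


@dataclass(frozen=True)
class EF:
    child: "CTLFormula"

    def __str__(self):
        return f"EF({self.child})"


@dataclass(frozen=True)
class AG:
    child: "CTLFormula"

    def __str__(self):
        return f"AG({self.child})"


CTLFormula = Union[Atom, And, Or, EF, AG]

#: The empty conjunction: satisfied by every state (φ_ε).
TRUE: CTLFormula = And(())


def subspace_formula(net: BooleanNetwork, p: SubspaceLike) -> CTLFormula:
    """φ_p: the conjunction of ``v = p(v)`` over the fixed variables of p
    (TRUE for ε)."""
    d = net.subspace(p)
    if not d:
        return TRUE
    return And(tuple(Atom("var", v, d[v]) for v in net.variables if v in d))


def _backward_closure(ts: TransitionSystem, target: set[int]) -> set[int]:
    """All states with a path into ``target`` (including target itself)."""
    reached = set(target)
    frontier = list(target)
    pred = ts.predecessors
    while frontier:
        x = frontier.pop()
        for y in pred[x]:
            if y not in reached:
                reached.add(y)
                frontier.append(y)
    return reached


def _sat(ts: TransitionSystem, phi: CTLFormula) -> set[int]:
    if isinstance(phi, Atom):
        if phi.kind == "var":
            hit = {x for x in range(ts.size) if ts.label_var(x, phi.var) == phi.value}
        else:
            hit = {x for x in range(ts.size) if ts.label_delta(x, phi.var) == phi.value}
        if phi.negated:
            return set(range(ts.size)) - hit
        return hit
    if isinstance(phi, And):
        out = set(range(ts.size))
        for a in phi.args:
            out &= _sat(ts, a)
        return out
    if isinstance(phi, Or):
        out: set[int] = set()
        for a in phi.args:
            out |= _sat(ts, a)
        return out
    if isinstance(phi, EF):
        return _backward_closure(ts, _sat(ts, phi.child))
    if isinstance(phi, AG):
        bad = set(range(ts.size)) - _sat(ts, phi.child)
        return set(range(ts.size)) - _backward_closure(ts, bad)
    raise TypeError(f"not a CTL formula: {phi!r}")


def sat_set(ts: TransitionSystem, phi: CTLFormula) -> set[str]:
    """The satisfaction set {x | x ⊧ φ} in codec-string form."""
    return {ts.decode(x) for x in _sat(ts, phi)}


@dataclass(frozen=True)
class Verdict:
    """Outcome of a model-checking query.

    ``counterexample`` is a violating initial state when the query fails;
    ``witness_path`` is a finite path starting at it (for a refuted
    disjunction of reachability targets the violating state itself is the
    "last state": no target is reachable from it).
    """

    holds: bool
    counterexample: Optional[str] = None
    witness_path: Optional[tuple[str, ...]] = None

    def __bool__(self):
        return self.holds


def _is_ef_disjunction(phi: CTLFormula) -> bool:
    if isinstance(phi, EF):
        return True
    return isinstance(phi, Or) and all(isinstance(a, EF) for a in phi.args)


def ctl_check(ts: TransitionSystem, phi: CTLFormula) -> Verdict:
    """Decide TS ⊧ φ (all initial states satisfy φ)."""
    good = _sat(ts, phi)
    bad = sorted(set(ts.init) - good)
    if not bad:
        return Verdict(True)
    witness = ts.decode(bad[0])
    path = (witness,) if _is_ef_disjunction(phi) else None
    return Verdict(False, counterexample=witness, witness_path=path)


# ---------------------------------------------------------------------------
# optional SMV text export (for cross-validation with external checkers)


def _smv_expr(e: Expression) -> str:
    from . import expressions as E

    if isinstance(e, E.Const):
        return "TRUE" if e.value else "FALSE"
    if isinstance(e, E.Var):
        return e.name
    if isinstance(e, E.Not):
        return f"!({_smv_expr(e.child)})"
    if isinstance(e, E.And):
        return "(" + " & ".join(_smv_expr(a) for a in e.args) + ")" if e.args else "TRUE"
    if isinstance(e, E.Or):
        return "(" + " | ".join(_smv_expr(a) for a in e.args) + ")" if e.args else "FALSE"
    raise TypeError(f"not an expression: {e!r}")


def _smv_formula(net: BooleanNetwork, phi: CTLFormula) -> str:
    if isinstance(phi, Atom):
        if phi.kind == "var":
            body = phi.var if phi.value else f"!{phi.var}"
        else:
            f = _smv_expr(net.functions[phi.var])
            v = phi.var
            body = {
                1: f"(!{v} & {f})",
                -1: f"({v} & !{f})",
                0: f"({v} <-> {f})",
            }[phi.value]
        return f"!{body}" if phi.negated else body
    if isinstance(phi, And):
        return "(" + " & ".join(_smv_formula(net, a) for a in phi.args) + ")" \
            if phi.args else "TRUE"
    if isinstance(phi, Or):
        return "(" + " | ".join(_smv_formula(net, a) for a in phi.args) + ")" \
            if phi.args else "FALSE"
    if isinstance(phi, EF):
        return f"EF({_smv_formula(net, phi.child)})"
    if isinstance(phi, AG):
        return f"AG({_smv_formula(net, phi.child)})"
    raise TypeError(f"not a CTL formula: {phi!r}")


def to_smv(net: BooleanNetwork, init: Optional[SubspaceLike] = None,
           spec: Optional[CTLFormula] = None) -> str:
    """Render the asynchronous system (and an optional query) as SMV text.

    Provided for cross-validation with external symbolic checkers; never
    used by the package itself.
    """
    lines = ["MODULE main", "VAR"]
    for v in net.variables:
        lines.append(f"  {v} : boolean;")
    if init is not None:
        d = net.subspace(init)
        if d:
            cond = " & ".join(v if d[v] else f"!{v}" for v in net.variables if v in d)
            lines.append(f"INIT {cond};")
    images = {v: _smv_expr(net.functions[v]) for v in net.variables}
    steady = " & ".join(f"({v} <-> {images[v]})" for v in net.variables)
    moves = []
    for v in net.variables:
        unchanged = " & ".join(
            f"(next({u}) <-> {u})" for u in net.variables if u != v
        )
        clause = f"(next({v}) <-> {images[v]}) & !(next({v}) <-> {v})"
        moves.append("(" + clause + (f" & {unchanged}" if unchanged else "") + ")")
    selfloop = "(" + " & ".join(
        f"(next({v}) <-> {v})" for v in net.variables
    ) + f" & ({steady})" + ")"
    lines.append("TRANS")
    lines.append("  " + " | ".join(moves + [selfloop]) + ";")
    if spec is not None:
        lines.append(f"CTLSPEC {_smv_formula(net, spec)};")
    return "\n".join(lines) + "\n"
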