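"""Approximation of asynchronous attractors by minimal trap spaces.

The minimal trap spaces min(S_F^⋆) approximate the attractors of the
asynchronous state transition graph.  Three criteria grade the
approximation, each decided by a reachability query of the CTL fragment:

* **faithful** — inside each trap space every attractor oscillates in all
  free dimensions: the reduced system satisfies ⋀_v EF(δ_v ≠ 0);
* **univocal** — each trap space contains exactly one attractor: one
  attractor state is reachable from every state of the reduced system;
* **complete** — no attractor lies outside the trap spaces: the full system
  satisfies ⋁_p EF(φ_p).

Faithfulness and univocality are checked on the reduced network of each
trap space.  The naive completeness query needs the full state space, which
is exactly what the *iterative refinement* avoids: starting from the
trivially complete {ε}, it repeatedly refines each working trap space by
the minimal trap spaces of restrictions to (extended) autonomous sets of
its reduced network, model checking completeness only on those restricted
systems.  A restriction whose minimal trap spaces are incomplete refutes
global completeness (failure criterion); when every working trap space has
been refined down to a minimal one, completeness is confirmed.
"""

from __future__ import annotations

import random
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, Field

from .dynamics import (
    DEFAULT_STATE_CAP,
    AG,
    Atom,
    And,
    EF,
    Or,
    Verdict,
    build_ts,
    ctl_check,
    random_walk,
    subspace_formula,
)
from .graphs import extend_autonomous
from .network import (
    BooleanNetwork,
    SubspaceLike,
    is_trap_space,
    lift_subspace,
    percolate,
    restrict,
    subspace_consistent,
    subspace_intersect,
    substitute,
)
from .traps import TrapSpaceSet, minimal_trap_spaces

__all__ = [
    "is_attractor_state",
    "find_attractor_state",
    "is_univocal",
    "is_faithful",
    "is_complete_naive",
    "failure_criterion",
    "intersect_complete_sets",
    "is_complete_iterative",
    "outside_attractors",
    "analyze",
    "CheckRecord",
    "RefinementStep",
    "RefinementTrace",
    "TrapSpaceVerdict",
    "ApproximationReport",
    "refinement_dot",
]


# ---------------------------------------------------------------------------
# projections


def _project(net: BooleanNetwork, sub: BooleanNetwork, x: SubspaceLike) -> str:
    """Project a state/subspace of ``net`` onto the variables of ``sub``."""
    d = net.subspace(x)
    return sub.format({v: d[v] for v in sub.variables if v in d})


# ---------------------------------------------------------------------------
# attractor states


def is_attractor_state(net: BooleanNetwork, p: SubspaceLike, x: SubspaceLike,
                       cap: int = DEFAULT_STATE_CAP) -> bool:
    """Whether state x ∈ S[p] belongs to an attractor of the asynchronous
    system.

    Decided on the reduced network of the trap space p: x is an attractor
    state iff its projection y satisfies AG(EF(φ_y)) from {y} — every state
    reachable from y can return to y, i.e. y lies in a terminal SCC.
    """
    d = net.subspace(p)
    if not is_trap_space(net, d):
        raise ValueError(f"{net.format(d)!r} is not a trap space")
    s = net.state(x)
    if any(s[v] != c for v, c in d.items()):
        raise ValueError(f"state {net.format(s)!r} lies outside {net.format(d)!r}")
    reduced = substitute(net, d)
    y = _project(net, reduced, s)
    ts = build_ts(reduced, "async", init=[y] if reduced.variables else "all", cap=cap)
    return ctl_check(ts, AG(EF(subspace_formula(reduced, y)))).holds


def _walk_then_verify(net: BooleanNetwork, p: SubspaceLike, seed: int,
                      start: Optional[str] = None,
                      cap: int = DEFAULT_STATE_CAP) -> str:
    """Random-walk inside trap space p until the endpoint verifies as an
    attractor state; the walk length doubles after every failed attempt."""
    d = net.subspace(p)
    rng = random.Random(seed)
    k = 10 * (net.n - len(d))
    for _ in range(64):
        sub_seed = rng.randrange(2**31)
        if start is None:
            x = random_walk(net, d, sub_seed, k=k)
        else:
            x = _walk_from(net, start, sub_seed, k=k)
        if is_attractor_state(net, d, x, cap=cap):
            return x
        k = max(2 * k, 2)
    raise RuntimeError("random walk failed to reach an attractor state")


def _walk_from(net: BooleanNetwork, x: str, seed: int, k: int) -> str:
    from .dynamics import successors_async

    rng = random.Random(seed)
    cur = net.format(net.state(x))
    for _ in range(k):
        succs = sorted(successors_async(net, cur))
        cur = succs[rng.randrange(len(succs))]
    return cur


def find_attractor_state(net: BooleanNetwork, p: SubspaceLike, seed: int,
                         cap: int = DEFAULT_STATE_CAP) -> str:
    """A state of S[p] that belongs to an attractor, found by a seeded
    random walk and verified by the attractor-state query.  Deterministic
    per seed."""
    return _walk_then_verify(net, p, seed, cap=cap)


# ---------------------------------------------------------------------------
# the three criteria


def is_univocal(net: BooleanNetwork, p: SubspaceLike, seed: int,
                cap: int = DEFAULT_STATE_CAP) -> bool:
    """Whether the trap space contains a unique attractor: one attractor
    state must be reachable from every state of the reduced system."""
    d = net.subspace(p)
    x = find_attractor_state(net, d, seed, cap=cap)
    reduced = substitute(net, d)
    if not reduced.variables:
        return True
    y = _project(net, reduced, x)
    ts = build_ts(reduced, "async", init="all", cap=cap)
    return ctl_check(ts, EF(subspace_formula(reduced, y))).holds


def is_faithful(net: BooleanNetwork, p: SubspaceLike,
                cap: int = DEFAULT_STATE_CAP) -> bool:
    """Whether every attractor in the trap space oscillates in all free
    dimensions: from every state of the reduced system, every free variable
    can eventually move (⋀_v EF(δ_v ≠ 0)).  Steady states satisfy the empty
    conjunction."""
    d = net.subspace(p)
    if not is_trap_space(net, d):
        raise ValueError(f"{net.format(d)!r} is not a trap space")
    reduced = substitute(net, d)
    if not reduced.variables:
        return True
    ts = build_ts(reduced, "async", init="all", cap=cap)
    phi = And(tuple(EF(Atom("delta", v, 0, negated=True))
                    for v in reduced.variables))
    return ctl_check(ts, phi).holds


def is_complete_naive(net: BooleanNetwork, P: Iterable[SubspaceLike],
                      cap: int = DEFAULT_STATE_CAP) -> Verdict:
    """The single-query completeness check on the full state space:
    TS = (S, ↪, S) ⊧ ⋁_p EF(φ_p).

    States inside ∪_p S[p] satisfy their own φ_p, so restricting the
    initial states to the outside is equivalent; a returned counterexample
    is always a state outside every S[p] that cannot reach any of them.
    """
    P = [net.subspace(p) for p in P]
    ts = build_ts(net, "async", init="all", cap=cap)
    phi = Or(tuple(EF(subspace_formula(net, p)) for p in P))
    return ctl_check(ts, phi)


def failure_criterion(net: BooleanNetwork, p: SubspaceLike,
                      cap: int = DEFAULT_STATE_CAP) -> bool:
    """Whether the trap space p refutes global completeness: the minimal
    trap spaces of the reduced network are not complete in the reduced
    system.  Trivially false for minimal trap spaces (their reduced
    networks are trap-space-free and {ε} is complete by definition)."""
    d = net.subspace(p)
    if not is_trap_space(net, d):
        raise ValueError(f"{net.format(d)!r} is not a trap space")
    reduced = substitute(net, d)
    if not reduced.variables:
        return False
    Q = minimal_trap_spaces(reduced)
    return not is_complete_naive(reduced, Q, cap=cap).holds


def intersect_complete_sets(net: BooleanNetwork,
                            P: Iterable[SubspaceLike],
                            Q: Iterable[SubspaceLike]) -> list[str]:
    """P ⊓ Q: all pairwise intersections of consistent members.

    If P and Q are complete sets of trap spaces, so is P ⊓ Q; with disjoint
    fixed variables |P ⊓ Q| = |P|·|Q|."""
    P = [net.subspace(p) for p in P]
    Q = [net.subspace(q) for q in Q]
    out = set()
    for p in P:
        for q in Q:
            if subspace_consistent(net, p, q):
                out.add(subspace_intersect(net, p, q))
    return sorted(out)


# ---------------------------------------------------------------------------
# iterative refinement


class CheckRecord(BaseModel):
    """One restricted system subjected to trap-space computation and, when
    non-trivial, completeness model checking."""

    variables: list[str]
    min_trap_spaces: list[str]
    complete: Optional[bool] = None  # None: trap-space-free, nothing to check
    counterexample: Optional[str] = None


class RefinementStep(BaseModel):
    popped: str
    previously_checked: list[str]
    percolated_to: Optional[str] = None
    checks: list[CheckRecord] = Field(default_factory=list)
    outcome: Literal["confirmed", "extended", "refined", "failed"]
    pushed: list[str] = Field(default_factory=list)
    confirmed: list[str] = Field(default_factory=list)
    percolation_deltas: dict[str, int] = Field(default_factory=dict)


class RefinementTrace(BaseModel):
    """Machine-readable record of the iterative completeness decision."""

    minimal_trap_spaces: list[str]
    steps: list[RefinementStep] = Field(default_factory=list)
    complete: Optional[bool] = None


def _fixed_count(net: BooleanNetwork, p: str) -> int:
    return len(net.subspace(p))


def _iterative_engine(net: BooleanNetwork, cap: int, stop_on_failure: bool):
    """Run the refinement loop.

    Returns ``(verdict, trace, failures)`` where ``failures`` is the list of
    (popped trap space, failing check) tuples; with ``stop_on_failure`` the
    loop returns at the first failure (the normal completeness decision),
    otherwise the failing branch is abandoned and the remaining branches are
    still explored (used for outside-attractor enumeration).
    """
    mints = minimal_trap_spaces(net)
    eps = net.format({})
    trace = RefinementTrace(minimal_trap_spaces=list(mints))
    if tuple(mints) == (eps,):
        trace.complete = True
        return Verdict(True), trace, []

    memo: dict = {}
    failures: list[tuple[str, CheckRecord]] = []
    current: list[tuple[str, frozenset]] = [(eps, frozenset())]
    while current:
        current.sort(key=lambda t: (t[0], sorted(t[1])))
        p, W = current.pop(0)
        step = RefinementStep(popped=p, previously_checked=sorted(W),
                              outcome="refined")
        trace.steps.append(step)

        r = percolate(net, p)
        if r != p:
            step.percolated_to = r
            step.percolation_deltas[r] = _fixed_count(net, r) - _fixed_count(net, p)
            p = r
        reduced = substitute(net, p)
        W = W & set(reduced.variables)
        if p in mints or not reduced.variables:
            step.outcome = "confirmed"
            step.confirmed.append(p)
            continue

        autonomous_sets = extend_autonomous(reduced, W)
        if not autonomous_sets:
            # cannot happen for non-minimal trap spaces of constant-free
            # reductions: exhausting all components implies trap-space-freeness
            raise RuntimeError(
                f"no autonomous sets left to refine {p!r} although it is "
                "not a minimal trap space"
            )
        found: list[tuple[BooleanNetwork, TrapSpaceSet]] = []
        checked = set(W)
        failed_here = False
        for U in autonomous_sets:
            rest = restrict(reduced, U)
            checked |= set(U)
            Q = minimal_trap_spaces(rest)
            record = CheckRecord(variables=sorted(U),
                                 min_trap_spaces=list(Q))
            step.checks.append(record)
            if tuple(Q) == (rest.format({}),):
                record.complete = None  # trap-space-free restriction
                continue
            key = (rest.to_bnet(), tuple(Q))
            if key not in memo:
                memo[key] = is_complete_naive(rest, Q, cap=cap)
            verdict = memo[key]
            record.complete = verdict.holds
            record.counterexample = verdict.counterexample
            if not verdict.holds:
                failures.append((p, record))
                failed_here = True
                if stop_on_failure:
                    step.outcome = "failed"
                    trace.complete = False
                    return (
                        Verdict(False, counterexample=verdict.counterexample),
                        trace,
                        failures,
                    )
                break
            found.append((rest, Q))
        if failed_here:
            step.outcome = "failed"
            continue
        if not found:
            # every restriction trap-space-free: extend and retry
            step.outcome = "extended"
            current.append((p, frozenset(checked)))
            step.pushed.append(p)
            continue
        # Refine: lift each complete set to the full network, intersect all
        # of them (and p itself), percolate each member.
        combo = [p]
        for rest, Q in found:
            lifted = [lift_subspace(net, rest, q) for q in Q]
            combo = intersect_complete_sets(net, combo, lifted)
        for q in combo:
            rq = percolate(net, q)
            step.percolation_deltas[rq] = _fixed_count(net, rq) - _fixed_count(net, q)
            if rq in mints:
                step.confirmed.append(rq)
            else:
                current.append((rq, frozenset()))
                step.pushed.append(rq)
    if failures:
        trace.complete = False
        return Verdict(False, counterexample=failures[0][1].counterexample), \
            trace, failures
    trace.complete = True
    return Verdict(True), trace, []


def is_complete_iterative(net: BooleanNetwork,
                          cap: int = DEFAULT_STATE_CAP
                          ) -> tuple[Verdict, RefinementTrace]:
    """Decide whether min(S_F^⋆) is complete without model checking the full
    state space.

    Works a set of (trap space, already-checked variables) tuples whose
    subspaces, together with the confirmed minimal trap spaces, always form
    a complete set.  Each iteration refines one tuple by the minimal trap
    spaces of restrictions to (extended) autonomous sets of its reduced
    network; an incomplete restriction refutes completeness outright.
    Completeness is confirmed when the working set empties.
    """
    verdict, trace, _ = _iterative_engine(net, cap, stop_on_failure=True)
    return verdict, trace


# ---------------------------------------------------------------------------
# outside attractors


def outside_attractors(net: BooleanNetwork, seed: int,
                       cap: int = DEFAULT_STATE_CAP) -> list[str]:
    """One representative state per attractor outside the minimal trap
    spaces (empty when the approximation is complete).

    For every trap space that fails the completeness refinement, the
    counterexample-driven loop walks from a violating state of the reduced
    system to an attractor, records a representative, adds it as a
    reachability target and repeats until the modified completeness query
    ⋁_z EF(φ_z) ∨ ⋁_q EF(φ_q) holds from every state.
    """
    mints = minimal_trap_spaces(net)
    verdict, trace, failures = _iterative_engine(net, cap, stop_on_failure=False)
    if verdict.holds:
        return []
    reps: list[str] = []
    rng = random.Random(seed)
    failing = sorted({p for p, _ in failures})
    for p in failing:
        d = net.subspace(p)
        reduced = substitute(net, d)
        ts = build_ts(reduced, "async", init="all", cap=cap)
        targets = [
            _project(net, reduced, net.subspace(subspace_intersect(net, m, d)))
            for m in mints
            if subspace_consistent(net, m, d)
        ]
        local: list[str] = []
        while True:
            phi = Or(
                tuple(EF(subspace_formula(reduced, t)) for t in targets)
                + tuple(EF(subspace_formula(reduced, z)) for z in local)
            )
            check = ctl_check(ts, phi)
            if check.holds:
                break
            z = _walk_then_verify(reduced, reduced.format({}),
                                  rng.randrange(2**31),
                                  start=check.counterexample, cap=cap)
            local.append(z)
        for z in local:
            full = dict(d)
            full.update(reduced.state(z))
            reps.append(net.format(full))
    reps = sorted(set(reps))
    if len(failing) > 1 and len(reps) > 1:
        reps = _dedupe_by_attractor(net, reps, cap)
    return reps


def _dedupe_by_attractor(net: BooleanNetwork, reps: list[str], cap: int) -> list[str]:
    """Drop representatives that share an attractor (mutual reachability in
    the full system); only needed when several failing branches overlap."""
    ts = build_ts(net, "async", init="all", cap=cap)
    kept: list[str] = []
    for r in reps:
        code = ts.encode(r)
        duplicate = False
        for k in kept:
            kc = ts.encode(k)
            if _reaches(ts, code, kc) and _reaches(ts, kc, code):
                duplicate = True
                break
        if not duplicate:
            kept.append(r)
    return kept


def _reaches(ts, a: int, b: int) -> bool:
    seen = {a}
    frontier = [a]
    while frontier:
        x = frontier.pop()
        if x == b:
            return True
        for y in ts.successors[x]:
            if y not in seen:
                seen.add(y)
                frontier.append(y)
    return False


# ---------------------------------------------------------------------------
# full analysis workflow


class TrapSpaceVerdict(BaseModel):
    trap_space: str
    steady: bool
    attractor_state: str
    univocal: bool
    faithful: bool


class ApproximationReport(BaseModel):
    """The complete approximation report for one network."""

    variables: list[str]
    minimal_trap_spaces: list[str]
    trap_spaces: list[TrapSpaceVerdict]
    complete: bool
    completeness_method: Literal["iterative", "naive"]
    outside_attractors: list[str]
    perfect: bool
    refinement: Optional[RefinementTrace] = None


def analyze(net: BooleanNetwork, seed: int = 0,
            method: Literal["iterative", "naive"] = "iterative",
            cap: int = DEFAULT_STATE_CAP) -> ApproximationReport:
    """The full workflow: minimal trap spaces, completeness, per-space
    univocality/faithfulness with a verified attractor state each, and
    outside-attractor representatives when incomplete.

    ``perfect`` is true when the approximation is faithful, univocal and
    complete — then every attractor corresponds one-to-one to a minimal trap
    space with exactly matching oscillating dimensions.
    """
    mints = minimal_trap_spaces(net)
    rng = random.Random(seed)
    trace: Optional[RefinementTrace] = None
    if method == "iterative":
        verdict, trace = is_complete_iterative(net, cap=cap)
    else:
        verdict = is_complete_naive(net, list(mints), cap=cap)
    per_space = []
    for p in mints:
        d = net.subspace(p)
        x = find_attractor_state(net, d, rng.randrange(2**31), cap=cap)
        per_space.append(TrapSpaceVerdict(
            trap_space=p,
            steady=len(d) == net.n,
            attractor_state=x,
            univocal=is_univocal(net, d, rng.randrange(2**31), cap=cap),
            faithful=is_faithful(net, d, cap=cap),
        ))
    outside = [] if verdict.holds else outside_attractors(
        net, rng.randrange(2**31), cap=cap)
    perfect = verdict.holds and all(v.univocal and v.faithful for v in per_space)
    return ApproximationReport(
        variables=list(net.variables),
        minimal_trap_spaces=list(mints),
        trap_spaces=per_space,
        complete=verdict.holds,
        completeness_method=method,
        outside_attractors=outside,
        perfect=perfect,
        refinement=trace,
    )


def refinement_dot(trace: RefinementTrace) -> str:
    """Render the refinement trace as a DOT decision tree: one node per
    popped trap space, arcs labelled by percolation deltas."""
    lines = ["digraph refinement {", "  node [shape=box];"]
    for i, step in enumerate(trace.steps):
        label = f"{step.popped}\\n{step.outcome}"
        lines.append(f'  s{i} [label="{label}"];')
    index_of: dict[str, int] = {}
    for i, step in enumerate(trace.steps):
        index_of.setdefault(step.popped, i)
    for i, step in enumerate(trace.steps):
        for child in step.pushed:
            for j in range(i + 1, len(trace.steps)):
                if trace.steps[j].popped == child:
                    delta = step.percolation_deltas.get(child, 0)
                    lines.append(f'  s{i} -> s{j} [label="+{delta}"];')
                    break
    lines.append("}")
    return "\n".join(lines) + "\n"
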