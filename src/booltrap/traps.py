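"""Minimal trap spaces.

The minimal trap spaces min(S_F^⋆) are the inclusion-minimal subspaces closed
under the dynamics; they contain every attractor candidate the approximation
is built from.  Steady states are exactly the fully fixed minimal trap
spaces, and every non-fixed minimal trap space contains only cyclic
attractors.

The main algorithm is a depth-first constraint search over partial
subspaces:

* *closure* — a free variable whose substituted function has become constant
  must be fixed to that constant (a minimal trap space always fixes it); a
  fixed variable whose function is constantly the opposite value kills the
  branch;
* *branching* — while some fixed variable's function is not yet constant,
  pick a free variable it depends on and branch three ways (0, 1, or
  "permanently free");
* *reduction* — once all fixed variables have constant-correct functions the
  partial assignment is a trap space, and everything below it is found by
  recursing on the reduced network.

Minimality is decided by pairwise comparison of the collected trap spaces.
A 3^n brute-force enumerator serves as the independent oracle at small n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Optional

from .network import (
    BooleanNetwork,
    SubspaceLike,
    is_trap_space,
    subspace_leq,
    substitute,
)

__all__ = [
    "TrapSpaceSet",
    "is_trap_space",
    "minimal_trap_spaces",
    "all_trap_spaces_bruteforce",
    "minimal_subset",
]


@dataclass(frozen=True)
class TrapSpaceSet:
    """A set of trap spaces of one network, in codec-string form.

    ``spaces`` is lexicographically sorted; ``minimal`` flags whether the set
    is the minimal trap spaces; ``truncated`` is set when an output cap cut
    the enumeration short.
    """

    spaces: tuple[str, ...]
    minimal: bool = False
    truncated: bool = False

    def __iter__(self) -> Iterator[str]:
        return iter(self.spaces)

    def __len__(self) -> int:
        return len(self.spaces)

    def __contains__(self, p) -> bool:
        return p in self.spaces


def _minimal_filter(net: BooleanNetwork, spaces) -> list[str]:
    spaces = sorted(set(spaces))
    out = []
    for p in spaces:
        if any(q != p and subspace_leq(net, q, p) for q in spaces):
            continue
        out.append(p)
    return out


def minimal_subset(net: BooleanNetwork, ts: TrapSpaceSet) -> TrapSpaceSet:
    """Extract the ≤-minimal members by pairwise comparison."""
    return TrapSpaceSet(tuple(_minimal_filter(net, ts.spaces)), minimal=True)


def _search_minimal(net: BooleanNetwork, collected: list[dict],
                    cap: Optional[int]) -> None:
    """Collect (into ``collected``) a superset of the minimal trap spaces of
    a network, as fixed-value dicts over ``net``'s variables."""

    variables = net.variables
    functions = net.functions

    def closure(p: dict) -> Optional[dict]:
        """Propagate forced fixings; return None when the branch dies."""
        p = dict(p)
        dirty = True
        while dirty:
            dirty = False
            for v in variables:
                c = functions[v].constancy(p)
                if v in p:
                    if c is not None and c != p[v]:
                        return None
                elif c is not None:
                    p[v] = c
                    dirty = True
        return p

    def recurse(p: dict, ff: frozenset) -> None:
        if cap is not None and len(collected) > cap:
            return
        p = closure(p)
        if p is None:
            return
        # permanently-free variables must stay free: a forced fixing there,
        # or an unresolved fixed function depending only on them, is fatal.
        unresolved = []
        for v, c in p.items():
            val = functions[v].constancy(p)
            if val is None:
                free_refs = [u for u in variables
                             if u in functions[v].variables() and u not in p]
                if all(u in ff for u in free_refs):
                    return
                unresolved.append((v, free_refs))
        if any(v in ff for v in p):
            return
        if not unresolved:
            if p:
                # p is a trap space; everything below it lives in the
                # reduced network, which is constant-free after closure.
                reduced = substitute(net, p)
                if not reduced.variables:
                    collected.append(p)
                    return
                inner = minimal_trap_spaces(reduced, max_spaces=cap)
                for q in inner:
                    collected.append({**p, **reduced.subspace(q)})
                return
            # p == ε: enumerate non-trivial trap spaces by branching on the
            # first variable not yet declared permanently free.
            branch = next((v for v in variables if v not in ff), None)
            if branch is None:
                return
        else:
            v, free_refs = unresolved[0]
            branch = next((u for u in free_refs if u not in ff), None)
            assert branch is not None  # otherwise caught above
        recurse({**p, branch: 0}, ff)
        recurse({**p, branch: 1}, ff)
        recurse(p, ff | {branch})

    recurse({}, frozenset())


def minimal_trap_spaces(net: BooleanNetwork,
                        max_spaces: Optional[int] = None) -> TrapSpaceSet:
    """Compute min(S_F^⋆), the inclusion-minimal trap spaces.

    Returns ``TrapSpaceSet({'--…-'}, minimal=True)`` exactly when the network
    is trap-space-free; every steady state appears as a fully fixed member.
    ``max_spaces`` caps the number of returned spaces (degenerate networks
    can have exponentially many); the ``truncated`` flag records a cut.
    """
    if not net.variables:
        return TrapSpaceSet(("",), minimal=True)
    collected: list[dict] = []
    _search_minimal(net, collected, max_spaces)
    spaces = _minimal_filter(net, (net.format(p) for p in collected))
    truncated = False
    if max_spaces is not None and len(spaces) > max_spaces:
        spaces = spaces[:max_spaces]
        truncated = True
    if not spaces:
        spaces = [net.format({})]  # trap-space-free: {ε}
    return TrapSpaceSet(tuple(spaces), minimal=True, truncated=truncated)


def all_trap_spaces_bruteforce(net: BooleanNetwork) -> TrapSpaceSet:
    """Enumerate all 3^n subspaces and keep the trap spaces (test oracle).

    Guarded to n ≤ 12.
    """
    if net.n > 12:
        raise ValueError(f"brute-force enumeration refused for n={net.n} > 12")
    spaces = []
    for cells in itertools.product("01-", repeat=net.n):
        p = "".join(cells)
        if is_trap_space(net, p):
            spaces.append(p)
    return TrapSpaceSet(tuple(sorted(spaces)), minimal=False)
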