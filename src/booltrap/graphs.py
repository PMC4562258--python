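"""Interaction graph structure: SCCs, condensation, autonomous sets.

The interaction graph has an arc u → v whenever f_v functionally depends on
u (there are two states differing only in u with different f_v values).  Its
strongly connected components split into *cascade components* — singletons
without a self-loop — and *non-cascade components*.  The condensation graph
(Z, ▹) keeps only the non-cascade components, connected whenever a path
between them passes through cascade vertices only, and stratifies them into
layers by longest-path depth.  Layer-1 components are exactly the minimal
autonomous sets (sets equal to their own regulator closure) of constant-free
networks; the refinement algorithm model checks their restrictions and
extends them layer by layer when restrictions are trap-space-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .expressions import depends_on
from .network import BooleanNetwork

__all__ = [
    "interaction_graph",
    "sccs",
    "above",
    "minimal_autonomous_sets",
    "CondensationGraph",
    "condensation",
    "extend_autonomous",
    "interaction_graph_dot",
    "condensation_dot",
]


def interaction_graph(net: BooleanNetwork) -> nx.DiGraph:
    """The functional-dependency digraph (V, →) of a network.

    Dependency of f_v on u is decided semantically by toggling u over all
    assignments of f_v's referenced variables, so syntactically mentioned but
    ineffective regulators produce no arc.
    """
    g = nx.DiGraph()
    g.add_nodes_from(net.variables)
    for v in net.variables:
        f = net.functions[v]
        for u in sorted(f.variables()):
            if depends_on(f, u):
                g.add_edge(u, v)
    return g


def sccs(g: nx.DiGraph) -> list[frozenset]:
    """The SCC partition of a digraph (singletons allowed), deterministically
    ordered by sorted member names."""
    return sorted(
        (frozenset(c) for c in nx.strongly_connected_components(g)),
        key=lambda c: sorted(c),
    )


def above(g: nx.DiGraph, U: Iterable) -> frozenset:
    """Above(U): U together with every vertex that has a path into U.

    A closure operator: monotone, extensive and idempotent.
    """
    U = set(U)
    unknown = U - set(g.nodes)
    if unknown:
        raise ValueError(f"unknown vertices {sorted(unknown)}")
    out = set(U)
    for u in U:
        out |= nx.ancestors(g, u)
    return frozenset(out)


def minimal_autonomous_sets(net: BooleanNetwork) -> list[frozenset]:
    """The inclusion-minimal autonomous sets: SCCs U with Above(U) = U."""
    g = interaction_graph(net)
    return [U for U in sccs(g) if above(g, U) == U]


@dataclass(frozen=True)
class CondensationGraph:
    """The condensation (Z, ▹) of an interaction graph.

    ``components`` are the non-cascade SCCs (deterministically ordered);
    ``graph`` is the DAG over component indices; ``layers[i]`` is the
    longest-path depth of component i (≥ 1); ``cascade`` lists the cascade
    singletons, which partition the remaining variables.
    """

    components: tuple[frozenset, ...]
    graph: nx.DiGraph
    layers: dict[int, int]
    cascade: tuple[frozenset, ...]

    def layer_one(self) -> list[frozenset]:
        return [self.components[i] for i in sorted(self.layers)
                if self.layers[i] == 1]


def _condense(g: nx.DiGraph) -> CondensationGraph:
    comps = sccs(g)
    cascade = tuple(
        c for c in comps
        if len(c) == 1 and not g.has_edge(next(iter(c)), next(iter(c)))
    )
    cascade_vertices = set().union(*cascade) if cascade else set()
    noncasc = tuple(c for c in comps if c not in set(cascade))
    dag = nx.DiGraph()
    dag.add_nodes_from(range(len(noncasc)))
    for i, U in enumerate(noncasc):
        for j, W in enumerate(noncasc):
            if i == j:
                continue
            # U ▹ W iff a path from U to W passes only through cascade
            # vertices in between; equivalent to reachability inside the
            # subgraph induced on U ∪ cascade ∪ W (any detour through U or W
            # vertices shortens to a compliant path).
            sub = g.subgraph(U | cascade_vertices | W)
            reach = set()
            for u in U:
                reach |= nx.descendants(sub, u)
            if reach & W:
                dag.add_edge(i, j)
    layers = {}
    for i in nx.topological_sort(dag):
        preds = list(dag.predecessors(i))
        layers[i] = 1 + max((layers[j] for j in preds), default=0)
    return CondensationGraph(noncasc, dag, layers, cascade)


def condensation(net: BooleanNetwork) -> CondensationGraph:
    """Condensation graph of the network's interaction graph."""
    return _condense(interaction_graph(net))


def extend_autonomous(net: BooleanNetwork, W: Iterable[str]) -> list[frozenset]:
    """Extended autonomous sets after the components meeting ``W`` have been
    explored.

    Removes every condensation component intersecting W, takes the layer-1
    components Y of the remaining DAG and returns Above(Y) in the interaction
    graph for each — one autonomous set per Y, deterministically ordered.
    Empty when no components remain.
    """
    W = set(W)
    g = interaction_graph(net)
    cond = _condense(g)
    keep = [i for i, U in enumerate(cond.components) if not (U & W)]
    sub = cond.graph.subgraph(keep)
    tops = [i for i in keep if not any(True for _ in sub.predecessors(i))]
    out = [above(g, cond.components[i]) for i in tops]
    return sorted(set(out), key=lambda s: sorted(s))


# ---------------------------------------------------------------------------
# DOT export (plain-text writers; no graphviz dependency)


def interaction_graph_dot(net: BooleanNetwork) -> str:
    """Interaction graph in DOT format, vertices grouped by SCC."""
    g = interaction_graph(net)
    lines = ["digraph interactions {"]
    for k, comp in enumerate(sccs(g)):
        lines.append(f"  subgraph cluster_{k} {{")
        for v in sorted(comp):
            lines.append(f'    "{v}";')
        lines.append("  }")
    for u, v in sorted(g.edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def condensation_dot(net: BooleanNetwork) -> str:
    """Condensation graph in DOT format with layers ranked."""
    cond = condensation(net)

    def label(c: frozenset) -> str:
        return "{" + ",".join(sorted(c)) + "}"

    lines = ["digraph condensation {", "  rankdir=TB;"]
    by_layer: dict[int, list[int]] = {}
    for i, lay in cond.layers.items():
        by_layer.setdefault(lay, []).append(i)
    for lay in sorted(by_layer):
        names = " ".join(f'"{label(cond.components[i])}"' for i in sorted(by_layer[lay]))
        lines.append(f"  {{ rank=same; {names} }}")
    for i, j in sorted(cond.graph.edges):
        lines.append(
            f'  "{label(cond.components[i])}" -> "{label(cond.components[j])}";'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
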