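"""Seeded random Boolean network generation.

Each variable receives ``k`` distinct regulators (fixed or Poisson-drawn
in-degree, self-inputs allowed) and a random truth table whose rows are 1
with probability ``bias``; the table is rendered as a disjunctive normal
form, so generated networks always round-trip through the ``.bnet`` codec.
Generation is fully deterministic per seed.  The defaults (mean in-degree
2, unbiased tables) produce the sparse, moderately coupled networks used
for the randomized validation suites.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass

from .expressions import And, Const, Not, Or, Var
from .network import BooleanNetwork

__all__ = ["GeneratorConfig", "generate_random_network", "random_network"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random network ensemble.

    ``n`` variables, in-degree parameter ``k`` (exact, or the Poisson mean
    with ``indegree="poisson"``), truth-table bias = probability of output 1,
    and the seed."""

    n: int
    k: int = 2
    seed: int = 0
    bias: float = 0.5
    indegree: str = "fixed"  # "fixed" | "poisson"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError("bias must lie in [0, 1]")
        if self.indegree not in ("fixed", "poisson"):
            raise ValueError(f"unknown in-degree mode {self.indegree!r}")


def _poisson(rng: random.Random, lam: float) -> int:
    # inverse-transform sampling; lam is small here
    import math

    u = rng.random()
    p = math.exp(-lam)
    cum, k = p, 0
    while u > cum:
        k += 1
        p *= lam / k
        cum += p
    return k


def _dnf_from_table(regs: list[str], rows: list[int]):
    """Render a truth table over ``regs`` as a DNF expression."""
    if not regs:
        return Const(rows[0])
    ones = [bits for bits, out in
            zip(itertools.product((0, 1), repeat=len(regs)), rows) if out]
    if not ones:
        return Const(0)
    if len(ones) == len(rows):
        return Const(1)
    terms = []
    for bits in ones:
        lits = [Var(r) if b else Not(Var(r)) for r, b in zip(regs, bits)]
        terms.append(lits[0] if len(lits) == 1 else And(lits))
    return terms[0] if len(terms) == 1 else Or(terms)


def generate_random_network(cfg: GeneratorConfig) -> BooleanNetwork:
    """Draw one network from the configured ensemble."""
    rng = random.Random(cfg.seed)
    variables = tuple(f"v{i}" for i in range(1, cfg.n + 1))
    functions = {}
    for v in variables:
        if cfg.indegree == "poisson":
            k = min(_poisson(rng, cfg.k), cfg.n, 8)
        else:
            k = min(cfg.k, cfg.n)
        regs = sorted(rng.sample(variables, k))
        rows = [1 if rng.random() < cfg.bias else 0 for _ in range(2 ** k)]
        functions[v] = _dnf_from_table(regs, rows)
    return BooleanNetwork(variables, functions)


def random_network(n: int, k: int = 2, seed: int = 0, **kw) -> BooleanNetwork:
    """Convenience wrapper around :func:`generate_random_network`."""
    return generate_random_network(GeneratorConfig(n=n, k=k, seed=seed, **kw))
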