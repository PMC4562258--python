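# booltrap

Approximating the asynchronous attractors of Boolean networks by their
minimal trap spaces, with model-checking-based quality certificates.

## The problem

Logical models of gene regulation and signalling are Boolean networks
(V, F): each variable `v` has an update function `f_v` over the variables,
and under the asynchronous rule one variable at a time moves toward its
function's value.  The long-term behaviours are the *attractors* — the
terminal strongly connected components of the state transition graph — but
enumerating them explicitly is hopeless beyond a few dozen variables.

A *trap space* is a subspace (a partial fixing of variables, written e.g.
`11--`) that the dynamics cannot leave; unlike general trap sets this is a
purely syntactic condition on the update functions, independent of the
update rule.  The inclusion-minimal trap spaces `min(S_F^⋆)` are cheap to
compute and every one contains at least one attractor, so they are a natural
*approximation* of the attractor landscape.  This package computes the
approximation and certifies its quality with three criteria:

* **faithful** — every attractor in a trap space `p` oscillates in exactly
  the free dimensions of `p` (its smallest enclosing subspace is `p`);
* **univocal** — each trap space contains exactly one attractor;
* **complete** — no attractor lies outside the trap spaces.

Each criterion is a reachability property of a small CTL fragment (atoms
`v = c` and `δ_v = d` with ∧, ∨, EF, AG), decided here by a native
explicit-state checker.  Faithfulness and univocality are checked on the
*reduced network* of each trap space.  The naive completeness query
`TS = (S, ↪, S) ⊧ ⋁_p EF(φ_p)` needs the full state space; the package's
centrepiece is an **iterative refinement** that avoids it: starting from the
trivially complete `{ε}`, each working trap space is refined by the minimal
trap spaces of restrictions to *autonomous sets* (variable sets containing
all their own regulators, found as top layers of the interaction graph's
condensation), model checking completeness only on those small restricted
systems.  An incomplete restriction refutes global completeness outright;
when every working space has been refined down to a minimal trap space,
completeness is confirmed.  If an approximation is faithful, univocal and
complete — *perfect* — the attractors correspond one-to-one to the minimal
trap spaces.

## Worked example

The six-variable model `coupled6` (two positive feedback loops driving a
negative loop) is bundled as a fixture:

```python
from booltrap import analyze, minimal_trap_spaces, percolate
from booltrap.fixtures import fixture

net = fixture("coupled6")
print(list(minimal_trap_spaces(net)))
# ['000000', '001100', '110010', '1111--']
print(percolate(net, "1100--"))
# 110010
print(analyze(net, seed=0).perfect)
# True
```

The four minimal trap spaces are three steady states plus `1111--`, whose
two free variables form a negative loop that oscillates forever; `analyze`
certifies that this is the complete attractor picture (`perfect = True`).
The three-variable fixture `incomplete3` shows the failure mode:

```python
from booltrap import is_complete_iterative, outside_attractors
net = fixture("incomplete3")
print(list(minimal_trap_spaces(net)))      # ['-00', '111']
print(is_complete_iterative(net)[0].holds)  # False
print(outside_attractors(net, seed=1))      # ['001']
```

`001` is a state of a cyclic attractor that no trap space predicts.

The same functionality is exposed as a thin CLI
(`booltrap trapspaces|attractors|check|oracle|generate|condense`), and the
`examples/` directory contains one narrative script per capability.

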