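# Methods

## Objects and conventions

A Boolean network is a pair (V, F) with an *ordered* variable tuple V and
one update function per variable.  The declaration order in the `.bnet`
source is authoritative: all bit-string codecs (states `110`, subspaces
`11-`) follow it, with `-` marking a free variable (`*` and `⋆` are accepted
on input).  States and subspaces cross the public API as codec strings or
as `{variable: bit}` dicts interchangeably.

The asynchronous transition relation moves exactly one variable per step
toward its function's value; fixed points carry a self-loop so every state
has a successor and infinite-path semantics are total.  Trap spaces are
decided *semantically*: `p` is a trap space iff for every fixed `v`,
`f_v[p]` is constantly `p(v)`, where constancy of a substituted expression
is established by a truth-table sweep over its remaining referenced
variables (substitution alone can leave non-simplified but constant
expressions such as `v | !v`).  The same semantic standard applies to the
interaction graph: an arc u → v exists only if `f_v` *functionally* depends
on u, and `restrict` accordingly tolerates (and substitutes away)
syntactically mentioned but ineffective out-of-set regulators.

## Minimal trap spaces

The search is a depth-first constraint propagation over partial subspaces:

1. **Closure.** A free variable whose substituted function has become
   constant is fixed to that constant — any inclusion-minimal trap space
   extending the branch must fix it.  A fixed variable whose substituted
   function is constantly the opposite value kills the branch, as does an
   unresolved obligation whose remaining support consists solely of
   variables declared permanently free.
2. **Branching.** While some fixed variable's function is not yet constant,
   a free variable from its support is branched three ways: 0, 1, or
   permanently free.  The three-way split partitions the subspace lattice,
   so no minimal trap space is missed.
3. **Reduction.** When every fixed variable's obligation holds, the partial
   assignment is a trap space; everything below it equals its intersection
   with the minimal trap spaces of the (constant-free) reduced network,
   computed recursively on strictly fewer variables.

Minimality is enforced by pairwise ≤-comparison of the collected spaces;
output order is lexicographic in the codec string.  A `max_spaces` cap
guards degenerate inputs (n independent self-activators have 2^n minimal
trap spaces); the returned set carries a `truncated` flag when it bites.
The search is validated against a 3^n brute-force enumeration (guarded to
n ≤ 12) on every fixture and on randomized ensembles.

## The CTL checker

The fragment (atoms, ∧, ∨, EF, AG) never requires syntactic negation:
atoms carry a polarity (`v ≠ c`, `δ_v ≠ d`), `Sat(EF φ)` is the backward
closure of `Sat(φ)` under the predecessor relation, and `Sat(AG φ)` is the
complement of the backward closure of the complement of `Sat(φ)` — the
complements act on computed state *sets*, which is sound for arbitrary
nesting within the fragment.  The checker is explicit-state with integer
bitmask codes; a configurable cap (default 25 variables) refuses systems
that would not fit an explicit representation.  Verdicts on failed queries
return a violating initial state; for refuted disjunctions of reachability
targets this state is exactly a state from which no target is reachable,
which is what counterexample-guided attractor enumeration needs.

An independent oracle (explicit per-state reachability evaluation of the
path semantics) cross-validates the checker on random transition systems
of ≤ 32 states over all fragment formulas up to depth 3.

## Criteria queries

With `p` a trap space, `(V_p, F_p)` its reduced network and `y` the
projection of a state `x`:

* attractor-state: `x` is in an attractor of `S[p]` iff the reduced system
  with initial state `{y}` satisfies `AG(EF(φ_y))`;
* univocal: some verified attractor state's projection is reachable from
  *all* states of the reduced system, `EF(φ_y)`;
* faithful: the reduced system satisfies `⋀_{v ∈ V_p} EF(δ_v ≠ 0)` (the
  empty conjunction makes steady states trivially faithful);
* complete (naive): the full system satisfies `⋁_p EF(φ_p)`.  Because the
  satisfaction set is computed globally, restricting initial states to the
  complement of the trap spaces is an equivalent formulation; returned
  counterexamples always lie in that complement.

Attractor states are found by seeded uniform random walks of length
10·|V_p| starting in `S[p]`, verified by the attractor-state query; on a
failed verification the walk restarts with doubled length (a bounded retry
loop — in practice the first walk almost always lands).  All randomness is
driven by caller-supplied seeds; derived sub-seeds stay below 2^31.

## Iterative completeness

The refinement state is a working set of tuples (p, W): a trap space and
the variables of its reduced network already subjected to model checking.
Invariant: the working subspaces plus the already-confirmed minimal trap
spaces form a complete set.  Each iteration (deterministic pop order:
lexicographic codec string):

1. percolate `p` in the full network (this also absorbs constant
   variables, so reduced networks are always constant-free); a percolation
   landing on a minimal trap space is confirmed directly;
2. build the reduced network, its condensation graph, and drop components
   intersecting W; for each remaining layer-1 component Y take the
   autonomous set U = Above(Y);
3. compute the minimal trap spaces Q of the restriction (U, F_p|U).  If all
   restrictions are trap-space-free, push (p, W ∪ checked) — the next pop
   extends deeper down the condensation.  If some Q is *incomplete* in its
   restricted system, global completeness is refuted (failure criterion).
4. otherwise intersect all complete sets found (consistent pairwise
   intersections), lift into the full network via `p ⊓ q`, percolate, and
   either confirm (minimal) or push back with W = ∅.

Repeated identical restricted-system checks are memoized on the
restriction's source text and trap-space set.  The trace — every pop,
check, percolation delta, push and confirmation — is a machine-readable
`RefinementTrace` (with an optional DOT decision-tree rendering) and is
included in the JSON analysis report.

When completeness fails, outside attractors are enumerated per failing
trap space `p` on its reduced system: the modified query
`⋁_z EF(φ_z) ∨ ⋁_q EF(φ_q)` over the minimal-trap-space targets plus the
representatives found so far is re-checked, and each counterexample state
seeds a verified walk to a new outside attractor, until the query holds.
The refutation reading of the modified query treats the found state `z` as
an additional *reachability* target (`EF(φ_z)`): a bare `φ_z` disjunct
would be trivially false on any reduced system with more than one
non-target state.  Representatives from distinct failing branches are
deduplicated by mutual reachability.  The enumeration runs the refinement
loop across all branches rather than stopping at the first failure, so
exactly one representative per missed attractor is produced (checked
against the explicit oracle at small n).

## Random network ensemble

The generator draws, per variable, k distinct regulators (fixed k, or
Poisson-distributed with mean k) and a random truth table whose rows are 1
with probability `bias`, rendered as DNF so every generated network
round-trips through the `.bnet` codec.  Defaults — k = 2, bias = 0.5 —
give sparse, moderately coupled ensembles comparable to published logical
models in connectivity.  The validation suite uses 200 networks with sizes
cycling over n = 3…10 and in-degrees over k = 1…3, which keeps exhaustive
3^n and 2^n oracles tractable while exercising all failure modes
(incompleteness, multivocality, unfaithfulness all occur in the ensemble).
What the generator does not emulate: canalyzing-function biases, scale-free
in-degree distributions and the strongly modular topologies of curated
pathway models — passing the randomized suites therefore certifies
algorithmic correctness, not biological typicality.

## Limitations

* All model checking is explicit-state; systems beyond the cap (default 25
  variables per *checked subsystem*) are refused rather than attempted.
  The refinement keeps checked subsystems small when the interaction graph
  is layered, but a single huge strongly connected component cannot be
  decomposed.
* The trap-space search is exponential in the worst case; it is intended
  for sparse networks at the scale of curated logical models (tens of
  variables), not for dense random graphs.
* Criteria are defined for the asynchronous rule only; the synchronous
  machinery exists for oracles and exploration.
* Multi-valued networks and signed interaction graphs are out of scope.
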