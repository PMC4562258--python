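"""Transition systems, attractor oracle, random walks, the CTL checker."""

import itertools
import random

import pytest

from booltrap import (
    AG,
    Atom,
    And,
    EF,
    Or,
    TRUE,
    StateCapExceeded,
    attractors_oracle,
    build_ts,
    ctl_check,
    parse_network,
    random_walk,
    sat_set,
    subspace_formula,
    successors_async,
    successors_sync,
    to_smv,
)
from booltrap.generate import random_network


class TestSuccessors:
    def test_xnor_pair_async(self, nets):
        assert successors_async(nets["xnor2"], "00") == {"10", "01"}

    def test_single_disagreeing_variable(self, nets):
        assert successors_async(nets["incomplete3"], "100") == {"000"}

    def test_fixed_point_self_loop(self, nets):
        assert successors_async(nets["coupled6"], "110010") == {"110010"}
        assert successors_sync(nets["coupled6"], "110010") == {"110010"}

    def test_sync_is_the_image(self, nets):
        assert successors_sync(nets["xnor2"], "00") == {"11"}
        assert successors_sync(nets["incomplete3"], "110") == {"101"}

    def test_async_moves_decrease_distance_to_image(self):
        # every asynchronous successor differs in one bit, toward F(x)
        for seed in range(10):
            net = random_network(5, 2, seed=seed)
            for x in net.states():
                y = net.image(x)
                for s in successors_async(net, x):
                    if s == x:
                        assert y == x
                        continue
                    diff = [i for i in range(5) if s[i] != x[i]]
                    assert len(diff) == 1 and s[diff[0]] == y[diff[0]]


class TestBuildTs:
    def test_explicit_graph_of_xnor_pair(self, nets):
        ts = build_ts(nets["xnor2"], "async")
        succ = {ts.decode(x): {ts.decode(y) for y in ts.successors_of(x)}
                for x in range(ts.size)}
        assert succ == {"00": {"10", "01"}, "01": {"00"},
                        "10": {"00"}, "11": {"11"}}

    def test_totality(self):
        for seed in range(10):
            net = random_network(5, 2, seed=seed)
            for rule in ("async", "sync"):
                ts = build_ts(net, rule)
                assert all(ts.successors_of(x) for x in range(ts.size))

    def test_self_activator_has_two_self_loops(self):
        ts = build_ts(parse_network("a, a"), "async")
        assert ts.successors_of(0) == (0,) and ts.successors_of(1) == (1,)

    def test_cap_guard(self):
        net = random_network(26, 1, seed=0)
        with pytest.raises(StateCapExceeded):
            build_ts(net, "async")

    def test_initial_states_from_subspace(self, nets):
        ts = build_ts(nets["incomplete3"], "async", init="-00")
        assert {ts.decode(x) for x in ts.init} == {"000", "100"}


class TestAttractorsOracle:
    def test_three_variable_example(self, nets):
        atts = attractors_oracle(nets["incomplete3"])
        assert sorted(sorted(a) for a in atts) == [
            ["000", "100"], ["001", "011", "101"], ["111"]]

    def test_xnor_pair(self, nets):
        atts = attractors_oracle(nets["xnor2"])
        assert sorted(sorted(a) for a in atts) == [["00", "01", "10"], ["11"]]

    def test_single_fixed_point_network(self):
        assert attractors_oracle(parse_network("a, 1\nb, a")) == [
            frozenset({"11"})]

    def test_attractors_are_closed_disjoint_and_reachable(self):
        for seed in range(10):
            net = random_network(6, 2, seed=seed)
            atts = attractors_oracle(net)
            for i, a in enumerate(atts):
                for x in a:
                    assert successors_async(net, x) <= a  # closed
                for b in atts[i + 1:]:
                    assert not (a & b)  # disjoint


class TestRandomWalk:
    def test_stays_inside_trap_space(self, nets):
        for seed in range(10):
            end = random_walk(nets["coupled6"], "1111--", seed)
            assert end.startswith("1111")

    def test_steady_state_returns_itself(self, nets):
        assert random_walk(nets["coupled6"], "110010", seed=3) == "110010"

    def test_deterministic_per_seed(self, nets):
        a = random_walk(nets["incomplete3"], "---", seed=7)
        assert a == random_walk(nets["incomplete3"], "---", seed=7)

    def test_long_walks_reach_the_attractor(self, nets):
        # -00 contains a unique 2-state attractor
        for seed in range(20):
            end = random_walk(nets["incomplete3"], "-00", seed, k=30)
            assert end in {"000", "100"}

    def test_non_trap_space_rejected(self, nets):
        with pytest.raises(ValueError, match="not a trap space"):
            random_walk(nets["incomplete3"], "1--", seed=0)


# ---------------------------------------------------------------------------
# CTL checker vs naive path semantics


def naive_sat(ts, phi):
    """Independent evaluation of the fragment semantics: EF via explicit
    forward reachability per state, AG via universality over the reachable
    set (totality makes infinite-path and reachability semantics agree)."""

    def reachable(x):
        seen = {x}
        stack = [x]
        while stack:
            cur = stack.pop()
            for y in ts.successors_of(cur):
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen

    if isinstance(phi, Atom):
        if phi.kind == "var":
            hit = {x for x in range(ts.size)
                   if ts.label_var(x, phi.var) == phi.value}
        else:
            hit = {x for x in range(ts.size)
                   if ts.label_delta(x, phi.var) == phi.value}
        return set(range(ts.size)) - hit if phi.negated else hit
    if isinstance(phi, And):
        out = set(range(ts.size))
        for a in phi.args:
            out &= naive_sat(ts, a)
        return out
    if isinstance(phi, Or):
        out = set()
        for a in phi.args:
            out |= naive_sat(ts, a)
        return out
    if isinstance(phi, EF):
        inner = naive_sat(ts, phi.child)
        return {x for x in range(ts.size) if reachable(x) & inner}
    if isinstance(phi, AG):
        inner = naive_sat(ts, phi.child)
        return {x for x in range(ts.size) if reachable(x) <= inner}
    raise TypeError(phi)


def random_formula(rng, variables, depth):
    if depth == 0 or rng.random() < 0.3:
        v = rng.choice(variables)
        if rng.random() < 0.5:
            return Atom("var", v, rng.randint(0, 1), negated=rng.random() < 0.3)
        return Atom("delta", v, rng.choice((-1, 0, 1)),
                    negated=rng.random() < 0.3)
    kind = rng.randrange(4)
    if kind == 0:
        return And(tuple(random_formula(rng, variables, depth - 1)
                         for _ in range(rng.randint(1, 2))))
    if kind == 1:
        return Or(tuple(random_formula(rng, variables, depth - 1)
                        for _ in range(rng.randint(1, 2))))
    if kind == 2:
        return EF(random_formula(rng, variables, depth - 1))
    return AG(random_formula(rng, variables, depth - 1))


class TestCtlChecker:
    def test_unreachable_fixed_point(self, nets):
        ts = build_ts(nets["xnor2"], "async")
        phi = EF(subspace_formula(nets["xnor2"], "11"))
        verdict = ctl_check(ts, phi)
        assert not verdict.holds
        # every state of the 3-cycle violates the query; 01 is one of them
        assert verdict.counterexample in {"00", "01", "10"}
        assert sat_set(ts, phi) == {"11"}

    def test_ef_true_everywhere(self, nets):
        ts = build_ts(nets["incomplete3"], "async")
        assert ctl_check(ts, EF(TRUE)).holds
        assert sat_set(ts, AG(TRUE)) == set(nets["incomplete3"].states())

    def test_fixed_point_recurrence(self, nets):
        ts = build_ts(nets["xnor2"], "async", init=["11"])
        assert ctl_check(ts, AG(EF(subspace_formula(nets["xnor2"], "11")))).holds

    def test_cycle_reaches_every_state(self):
        # deterministic 4-cycle: the reduction of the input combination 11
        net = parse_network("v3, !v4\nv4, v3")
        ts = build_ts(net, "async")
        for target in net.states():
            assert sat_set(ts, EF(subspace_formula(net, target))) == \
                set(net.states())

    def test_ef_monotone_ag_deflationary(self):
        rng = random.Random(5)
        for seed in range(10):
            net = random_network(4, 2, seed=seed)
            ts = build_ts(net, "async")
            phi = random_formula(rng, list(net.variables), 2)
            base = sat_set(ts, phi)
            assert base <= sat_set(ts, EF(phi))
            assert sat_set(ts, AG(phi)) <= base

    @pytest.mark.parametrize("rule", ["async", "sync"])
    def test_agrees_with_naive_semantics(self, rule):
        rng = random.Random(42)
        for seed in range(12):
            net = random_network(rng.randint(2, 5), rng.randint(1, 3),
                                 seed=seed)
            ts = build_ts(net, rule)
            for _ in range(8):
                phi = random_formula(rng, list(net.variables), 3)
                got = {ts.decode(s) for s in naive_sat(ts, phi)}
                assert sat_set(ts, phi) == got, str(phi)

    def test_attractor_membership_formula(self):
        # x is an attractor state iff x ⊧ AG(EF(φ_x))
        for seed in range(8):
            net = random_network(4, 2, seed=seed)
            ts = build_ts(net, "async")
            members = set().union(*attractors_oracle(net))
            for x in net.states():
                phi = AG(EF(subspace_formula(net, x)))
                assert (x in sat_set(ts, phi)) == (x in members)


class TestSmvExport:
    def test_text_structure(self, nets):
        net = nets["xnor2"]
        text = to_smv(net, init="1-",
                      spec=AG(EF(subspace_formula(net, "11"))))
        assert "MODULE main" in text
        assert "v1 : boolean;" in text
        assert "TRANS" in text
        assert "CTLSPEC AG(EF((v1 & v2)));" in text
        assert "INIT v1;" in text
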