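"""The three criteria, the refinement algorithm and the full workflow,
cross-validated against the explicit attractor oracle."""

import pytest

from booltrap import (
    analyze,
    attractors_oracle,
    failure_criterion,
    find_attractor_state,
    intersect_complete_sets,
    is_attractor_state,
    is_complete_iterative,
    is_complete_naive,
    is_faithful,
    is_univocal,
    lift_subspace,
    minimal_trap_spaces,
    outside_attractors,
    parse_network,
    refinement_dot,
    restrict,
    subspace_leq,
    validate_report,
)
from booltrap.generate import random_network


def smallest_subspace(net, attractor):
    """Sub(A): the smallest subspace containing a set of states (oracle)."""
    fixed = {}
    for i, v in enumerate(net.variables):
        values = {x[i] for x in attractor}
        if len(values) == 1:
            fixed[v] = int(values.pop())
    return net.format(fixed)


def oracle_verdicts(net):
    """Ground-truth criteria from the explicit attractor oracle."""
    atts = attractors_oracle(net)
    mints = list(minimal_trap_spaces(net))
    inside = {
        p: [a for a in atts
            if all(subspace_leq(net, x, p) for x in a)]
        for p in mints
    }
    faithful = {p: all(smallest_subspace(net, a) == p for a in inside[p])
                for p in mints}
    univocal = {p: len(inside[p]) == 1 for p in mints}
    complete = all(any(all(subspace_leq(net, x, p) for x in a)
                       for p in mints) for a in atts)
    outside = [a for a in atts
               if not any(all(subspace_leq(net, x, p) for x in a)
                          for p in mints)]
    return faithful, univocal, complete, outside


class TestAttractorState:
    def test_steady_state_qualifies(self, nets):
        assert is_attractor_state(nets["incomplete3"], "---", "111")

    def test_transient_state_rejected(self, nets):
        assert not is_attractor_state(nets["incomplete3"], "---", "110")

    def test_deterministic_cycle_every_state_qualifies(self, nets):
        # inside 11-- the reduction of inputs4 is a 4-cycle
        for x in ("1100", "1101", "1110", "1111"):
            assert is_attractor_state(nets["inputs4"], "11--", x)

    def test_state_outside_trap_space_rejected(self, nets):
        with pytest.raises(ValueError, match="outside"):
            is_attractor_state(nets["incomplete3"], "-00", "111")

    def test_find_returns_verified_state(self, nets):
        x = find_attractor_state(nets["incomplete3"], "-00", seed=0)
        assert x in {"000", "100"}
        assert find_attractor_state(nets["coupled6"], "110010", seed=1) == \
            "110010"
        assert find_attractor_state(nets["coupled6"], "1111--", seed=2) \
            .startswith("1111")

    def test_find_is_deterministic(self, nets):
        a = find_attractor_state(nets["incomplete3"], "---", seed=9)
        assert a == find_attractor_state(nets["incomplete3"], "---", seed=9)


class TestUnivocal:
    def test_unique_oscillation(self, nets):
        assert is_univocal(nets["incomplete3"], "-00", seed=0)

    def test_two_attractors_in_one_space(self, nets):
        assert not is_univocal(nets["xnor2"], "--", seed=0)

    def test_steady_state_trivially_univocal(self, nets):
        assert is_univocal(nets["coupled6"], "110010", seed=0)


class TestFaithful:
    def test_negative_loop_oscillates_both_dimensions(self, nets):
        assert is_faithful(nets["coupled6"], "1111--")

    def test_steady_state_empty_conjunction(self, nets):
        assert is_faithful(nets["coupled6"], "000000")

    def test_steady_variable_in_free_dimension(self, nets):
        assert not is_faithful(nets["unfaithful3"], "---")


class TestCompleteness:
    def test_missed_attractor_detected(self, nets):
        net = nets["incomplete3"]
        verdict = is_complete_naive(net, list(minimal_trap_spaces(net)))
        assert not verdict.holds
        assert verdict.counterexample in {"001", "011", "101"}

    def test_input_network_complete(self, nets):
        net = nets["inputs4"]
        assert is_complete_naive(net, list(minimal_trap_spaces(net))).holds

    def test_trivial_set_is_complete(self, nets):
        assert is_complete_naive(nets["incomplete3"], ["---"]).holds

    def test_failure_criterion_examples(self, nets):
        assert failure_criterion(nets["incomplete3"], "--1")
        assert not failure_criterion(nets["incomplete3"], "-00")
        assert not failure_criterion(nets["unfaithful3"], "---")


class TestIntersectCompleteSets:
    def test_lifted_feedback_loop_sets(self, nets):
        net = nets["coupled6"]
        q1 = [lift_subspace(net, restrict(net, ["v1", "v2"]), q)
              for q in minimal_trap_spaces(restrict(net, ["v1", "v2"]))]
        q2 = [lift_subspace(net, restrict(net, ["v3", "v4"]), q)
              for q in minimal_trap_spaces(restrict(net, ["v3", "v4"]))]
        assert intersect_complete_sets(net, q1, q2) == [
            "0000--", "0011--", "1100--", "1111--"]

    def test_epsilon_is_neutral(self, nets):
        net = nets["incomplete3"]
        assert intersect_complete_sets(net, ["-00", "111"], ["---"]) == \
            ["-00", "111"]

    def test_disjoint_fixings_multiply(self, nets):
        net = nets["inputs4"]
        out = intersect_complete_sets(net, ["0---", "1---"],
                                      ["-0--", "-1--"])
        assert len(out) == 4


class TestIterative:
    def test_incomplete_example(self, nets):
        verdict, trace = is_complete_iterative(nets["incomplete3"])
        assert not verdict.holds and trace.complete is False
        assert trace.steps[-1].outcome == "failed"

    def test_input_example_trace(self, nets):
        verdict, trace = is_complete_iterative(nets["inputs4"])
        assert verdict.holds
        first = trace.steps[0]
        # the two input singletons are checked and the four input
        # combinations are produced by intersection
        assert [c.variables for c in first.checks] == [["v1"], ["v2"]]
        produced = first.pushed + first.confirmed
        assert sorted(produced) == ["0000", "0100", "1010", "11--"]

    def test_two_loop_example_trace(self, nets):
        verdict, trace = is_complete_iterative(nets["coupled6"])
        assert verdict.holds
        first = trace.steps[0]
        assert [c.variables for c in first.checks] == [
            ["v1", "v2"], ["v3", "v4"]]
        assert all(c.min_trap_spaces == ["00", "11"] and c.complete
                   for c in first.checks)
        assert sorted(first.pushed + first.confirmed) == [
            "000000", "001100", "110010", "1111--"]

    def test_extension_step(self, nets):
        verdict, trace = is_complete_iterative(nets["cascade3"])
        assert verdict.holds
        assert trace.steps[0].outcome == "extended"
        assert trace.steps[0].checks[0].variables == ["v1", "v2"]
        assert trace.steps[0].checks[0].complete is None  # trap-space-free
        assert trace.steps[1].checks[0].variables == ["v1", "v2", "v3"]

    def test_trap_space_free_network_trivially_complete(self, nets):
        verdict, trace = is_complete_iterative(nets["unfaithful3"])
        assert verdict.holds and trace.steps == []

    def test_dot_export_of_trace(self, nets):
        _, trace = is_complete_iterative(nets["inputs4"])
        dot = refinement_dot(trace)
        assert dot.startswith("digraph") and "----" in dot


class TestOutsideAttractors:
    def test_one_representative_for_missed_cycle(self, nets):
        reps = outside_attractors(nets["incomplete3"], seed=1)
        assert len(reps) == 1 and reps[0] in {"001", "011", "101"}

    def test_complete_networks_have_none(self, nets):
        assert outside_attractors(nets["inputs4"], seed=0) == []
        assert outside_attractors(nets["unfaithful3"], seed=0) == []


class TestAnalyze:
    def test_perfect_approximation(self, nets):
        report = analyze(nets["coupled6"], seed=0)
        assert report.perfect and report.complete
        steady = [t for t in report.trap_spaces if t.steady]
        cyclic = [t for t in report.trap_spaces if not t.steady]
        assert len(steady) == 3 and len(cyclic) == 1
        assert cyclic[0].trap_space == "1111--"

    def test_incomplete_network_not_perfect(self, nets):
        report = analyze(nets["incomplete3"], seed=0)
        assert not report.complete and not report.perfect
        assert len(report.outside_attractors) == 1

    def test_unfaithful_network(self, nets):
        report = analyze(nets["unfaithful3"], seed=0)
        assert report.complete
        assert all(t.univocal for t in report.trap_spaces)
        assert not any(t.faithful for t in report.trap_spaces)
        assert not report.perfect

    def test_report_json_roundtrip(self, nets):
        report = analyze(nets["inputs4"], seed=0, method="naive")
        again = validate_report(report.model_dump_json())
        assert again == report


class TestOracleEquivalence:
    """CTL verdicts must equal the ground truth derived from terminal SCCs."""

    @pytest.mark.parametrize("n, k", [(4, 1), (5, 2), (6, 3), (7, 2)])
    def test_criteria_match_attractor_oracle(self, n, k):
        for seed in range(10):
            net = random_network(n, k, seed=7000 + 100 * n + seed)
            faithful, univocal, complete, outside = oracle_verdicts(net)
            mints = list(minimal_trap_spaces(net))
            for p in mints:
                assert is_faithful(net, p) == faithful[p], net.to_bnet()
                assert is_univocal(net, p, seed=seed) == univocal[p]
            naive = is_complete_naive(net, mints).holds
            iterative, _ = is_complete_iterative(net)
            assert naive == complete
            assert iterative.holds == complete
            reps = outside_attractors(net, seed=seed)
            assert len(reps) == len(outside)
            for r in reps:
                assert any(r in a for a in outside)

    def test_refinement_invariant_covers_all_attractors(self):
        # after every step, confirmed minimal trap spaces plus working
        # subspaces contain every attractor
        from booltrap.approximation import _iterative_engine

        for seed in range(10):
            net = random_network(6, 2, seed=seed)
            atts = attractors_oracle(net)
            verdict, trace, _ = _iterative_engine(net, 25, True)
            if not verdict.holds:
                continue
            covered: list[str] = []
            working = ["-" * net.n]
            for step in trace.steps:
                working = [p for p in working if p != step.popped]
                working += step.pushed
                covered += step.confirmed
                for a in atts:
                    assert any(
                        all(subspace_leq(net, x, p) for x in a)
                        for p in covered + working
                    )

    def test_every_minimal_trap_space_contains_an_attractor(self):
        for seed in range(10):
            net = random_network(6, 2, seed=100 + seed)
            atts = attractors_oracle(net)
            for p in minimal_trap_spaces(net):
                inside = [a for a in atts
                          if all(subspace_leq(net, x, p) for x in a)]
                assert inside
                if "-" not in p:
                    assert inside == [frozenset({p})]
                else:
                    assert all(len(a) > 1 for a in inside)
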