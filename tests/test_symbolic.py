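from __future__ import annotations

import random
from fractions import Fraction

import pytest

import temkit as tk
from temkit.irs import IRS
from temkit.linconstr import Constraint, implies, is_satisfiable, parse_constraint, sample_point
from temkit.symbolic import SymbolicState, initial_poly, interval_feasible, pattern_matches

from conftest import generous_params

F = Fraction


def C(text):
    return parse_constraint(text)


def state_with_clocks(tem, location, values, extra_clocks=()):
    cons = [Constraint.equality(tk.clock_name(v), F(x)) for v, x in values.items()]
    for name in extra_clocks:
        cons.append(Constraint.equality(name, 0))
    clocks = frozenset(tem.clocks) | frozenset(extra_clocks)
    universe = clocks | set(tem.param_names())
    from temkit.linconstr import System

    poly = System.of(cons, universe).conjoin(tem.invariant(location))
    return SymbolicState(location, poly, clocks)


class TestTimeElapse:
    def test_clock_difference_is_preserved(self, two_gene_tem):
        s = state_with_clocks(two_gene_tem, ("+", "+"), {"x": 7, "y": 12})
        out = tk.time_elapse(s, two_gene_tem)
        assert implies(out.poly, C("h_y - h_x = 5"))
        assert implies(out.poly, C("h_x >= 7"))

    def test_enabled_exactly_at_min_delay_minus_seven(self, two_gene_tem):
        # track elapsed time with an auxiliary clock starting at 0
        s = state_with_clocks(two_gene_tem, ("+", "+"), {"x": 7, "y": 12},
                              extra_clocks=("elapsed",))
        out = tk.time_elapse(s, two_gene_tem)
        edge = next(e for e in two_gene_tem.edges
                    if e.source == ("+", "+") and e.flipped == "x")
        stepped = tk.discrete_step(out, edge, two_gene_tem)
        # the step happens exactly when elapsed >= t_inc_min_x - 7
        assert implies(stepped.poly, C("elapsed >= t_inc_min_x - 7"))
        assert is_satisfiable(stepped.poly.conjoin(
            [C("t_inc_min_x = 9"), C("elapsed = 2")]))
        assert not is_satisfiable(stepped.poly.conjoin(
            [C("t_inc_min_x = 9"), C("elapsed <= 1")]))

    def test_invariant_violation_empties(self, two_gene_tem):
        s = state_with_clocks(two_gene_tem, ("+", "+"), {"x": 7, "y": 12})
        s = SymbolicState(s.location, s.poly.conjoin([C("t_inc_max_x = 5")]), s.clocks)
        out = tk.time_elapse(s, two_gene_tem)
        assert not is_satisfiable(out.poly)

    def test_unbounded_without_invariant(self):
        tem = tk.build_tem(
            tk.two_gene_irs(),
            infinite_max={("x", "+"), ("x", "-"), ("y", "+"), ("y", "-")},
        )
        s = state_with_clocks(tem, ("+", "+"), {"x": 0, "y": 0})
        out = tk.time_elapse(s, tem)
        assert is_satisfiable(out.poly.conjoin([C("h_x = 1000000")]))


class TestDiscreteStep:
    def test_reset_postcondition(self, two_gene_tem):
        s = state_with_clocks(two_gene_tem, ("+", "+"), {"x": 7, "y": 12})
        edge = next(e for e in two_gene_tem.edges
                    if e.source == ("+", "+") and e.flipped == "x")
        out = tk.discrete_step(tk.time_elapse(s, two_gene_tem), edge, two_gene_tem)
        assert implies(out.poly, C("h_x = 0"))
        assert out.location == ("-", "+")
        assert out.trace == ("x",)

    def test_unreachable_guard_empties(self, two_gene_tem):
        s = state_with_clocks(two_gene_tem, ("+", "+"), {"x": 7, "y": 12})
        s = SymbolicState(s.location, s.poly.conjoin([C("t_inc_min_x = 9")]), s.clocks)
        edge = next(e for e in two_gene_tem.edges
                    if e.source == ("+", "+") and e.flipped == "x")
        out = tk.discrete_step(s, edge, two_gene_tem)  # no elapse first
        assert not is_satisfiable(out.poly)

    def test_sign_precondition_contradiction_empties(self, two_gene_tem):
        s = state_with_clocks(two_gene_tem, ("+", "+"), {"x": 7, "y": 12})
        edge = next(e for e in two_gene_tem.edges
                    if e.source == ("+", "+") and e.flipped == "x")
        ann = tk.TimingAnnotation("x", "high", sign_preconditions=(("y", "-"),))
        out = tk.discrete_step(tk.time_elapse(s, two_gene_tem), edge, two_gene_tem, [ann])
        assert not is_satisfiable(out.poly)

    def test_annotation_conditions_conjoined_on_matching_edge_only(self, two_gene_tem):
        ann = tk.TimingAnnotation("x", "high", clock_conditions=(C("h_y = 2"),))
        s = state_with_clocks(two_gene_tem, ("+", "+"), {"x": 0, "y": 0})
        elapsed = tk.time_elapse(s, two_gene_tem)
        x_edge = next(e for e in two_gene_tem.edges
                      if e.source == ("+", "+") and e.flipped == "x")
        out = tk.discrete_step(elapsed, x_edge, two_gene_tem, [ann])
        assert implies(out.poly, C("h_y = 2"))
        # the same annotation does not constrain y's peak
        s2 = state_with_clocks(two_gene_tem, ("+", "-"), {"x": 0, "y": 0})
        y_edge = next(e for e in two_gene_tem.edges
                      if e.source == ("+", "-") and e.flipped == "y")
        out2 = tk.discrete_step(tk.time_elapse(s2, two_gene_tem), y_edge,
                                two_gene_tem, [ann])
        assert not implies(out2.poly, C("h_x = 2"))
        assert is_satisfiable(out2.poly)

    def test_wrong_source_raises(self, two_gene_tem):
        s = state_with_clocks(two_gene_tem, ("+", "+"), {"x": 0, "y": 0})
        edge = next(e for e in two_gene_tem.edges if e.source == ("-", "-"))
        with pytest.raises(ValueError):
            tk.discrete_step(s, edge, two_gene_tem)


class TestMatchPaths:
    def test_two_gene_exact_cycle(self, two_gene_tem, two_gene_cycle):
        paths = tk.match_paths(two_gene_tem, two_gene_cycle, max_len=4)
        assert len(paths) == 1
        assert [e.flipped for e in paths[0]] == ["y", "x", "y", "x"]

    def test_contradictory_first_waypoint(self, two_gene_tem):
        spec = tk.CycleSpec.of([{"x": "-", "y": "+"}, {"x": "-", "y": "-"}])
        # initial location is (+,-): first waypoint only matches later
        paths = tk.match_paths(two_gene_tem, spec, max_len=1)
        assert paths == []

    def test_paths_verified_by_naive_matcher(self, circadian_tem):
        spec = tk.CycleSpec.of(
            [
                {"M_P": "+", "M_T": "+"},
                {"M_P": "+", "M_T": "-"},
                {"M_P": "-", "M_T": "-"},
                {"M_P": "+", "M_T": "-"},
                {"M_P": "+", "M_T": "+"},
            ]
        )
        paths = tk.match_paths(circadian_tem, spec, max_len=6)
        assert paths  # realizable discretely
        comps = circadian_tem.components
        for path in paths:
            locs = [circadian_tem.initial] + [e.target for e in path]
            # greedy independent re-scan
            idx = 0
            for loc in locs:
                while idx < len(spec.waypoints) and pattern_matches(
                    spec.waypoints[idx], loc, comps
                ):
                    idx += 1
            assert idx == len(spec.waypoints)

    def test_empty_hop_allowed(self, two_gene_tem):
        spec = tk.CycleSpec.of([{"x": "+"}, {"y": "-"}])  # both match the start
        paths = tk.match_paths(two_gene_tem, spec, max_len=2)
        assert [] in [list(p) for p in paths]


class TestDeriveParameterRegion:
    def test_region_entails_structural(self, two_gene_tem, two_gene_cycle):
        res = tk.derive_parameter_region(two_gene_tem, two_gene_cycle, max_len=4)
        assert res.realizable
        for c in tk.structural_constraints(two_gene_tem):
            assert res.region.entails(c)

    def test_agrees_with_concrete_oracle_on_grid(self, two_gene_tem, two_gene_cycle):
        res = tk.derive_parameter_region(
            two_gene_tem, two_gene_cycle, init="zero", max_len=4
        )
        rng = random.Random(42)
        for _ in range(12):
            params = {}
            for v in two_gene_tem.components:
                for phase in "+-":
                    a, b = sorted([F(rng.randint(0, 6)), F(rng.randint(0, 6))])
                    params[tk.param_name(v, phase, "min")] = a
                    params[tk.param_name(v, phase, "max")] = b
            expected = tk.run_exists(
                two_gene_tem, params, two_gene_cycle, max_len=4
            ) is not None
            assert res.region.contains(params) == expected

    def test_forced_zero_min_delay(self, two_gene_tem):
        # pinning a peak at clock value 0 forces the min delay to be 0
        spec = tk.CycleSpec.of([{"x": "+", "y": "+"}, {"x": "-", "y": "+"}])
        ann = tk.TimingAnnotation("x", "high", clock_conditions=(C("h_x = 0"),))
        tem = tk.build_tem(tk.two_gene_irs(), ("+", "+"))
        res = tk.derive_parameter_region(tem, spec, [ann], init="zero", max_len=2)
        assert res.realizable
        assert res.region.entails(C("t_inc_min_x = 0"))

    def test_unrealizable_reported_distinctly(self, two_gene_tem):
        spec = tk.CycleSpec.of([{"x": "-", "y": "+"}, {"x": "+", "y": "+"}])
        res = tk.derive_parameter_region(two_gene_tem, spec, max_len=0)
        assert not res.realizable
        assert res.region.is_empty
        assert res.n_paths == 0

    def test_monotone_in_bound(self):
        rng = random.Random(9)
        for seed in range(6):
            irs = tk.random_irs(2, 2, 1, seed=seed)
            tem = tk.build_tem(irs)
            spec = tk.CycleSpec.of(
                [dict(zip(irs.components, tem.initial)),
                 {irs.components[0]: "-"}]
            )
            small = tk.derive_parameter_region(tem, spec, init="zero", max_len=3)
            large = tk.derive_parameter_region(tem, spec, init="zero", max_len=4)
            # every disjunct of the smaller region lies inside the larger one
            for d in small.region.disjuncts:
                point = sample_point(d)
                assert point is not None
                assert large.region.contains(
                    {v: point.get(v, F(0)) for v in large.region.universe}
                )

    def test_zone_and_path_engines_agree(self, two_gene_tem, two_gene_cycle):
        for init in ("zero", "symbolic"):
            a = tk.derive_parameter_region(
                two_gene_tem, two_gene_cycle, init=init, max_len=5, engine="zone"
            )
            b = tk.derive_parameter_region(
                two_gene_tem, two_gene_cycle, init=init, max_len=5, engine="path"
            )
            assert [str(d) for d in a.region.disjuncts] == [
                str(d) for d in b.region.disjuncts
            ]

    def test_engines_agree_on_random_models(self):
        for seed in (1, 3, 5, 8):
            irs = tk.random_irs(2, 2, 1, seed=seed)
            tem = tk.build_tem(irs)
            a_name, b_name = irs.components
            spec = tk.CycleSpec.of(
                [dict(zip(irs.components, tem.initial)), {a_name: "-"}]
            )
            a = tk.derive_parameter_region(tem, spec, init="zero", max_len=4,
                                           engine="zone")
            b = tk.derive_parameter_region(tem, spec, init="zero", max_len=4,
                                           engine="path")
            assert [str(d) for d in a.region.disjuncts] == [
                str(d) for d in b.region.disjuncts
            ]


class TestCheckPeriod:
    def test_requires_closed_spec(self, two_gene_tem):
        spec = tk.CycleSpec.of([{"x": "+"}, {"x": "-"}])
        with pytest.raises(ValueError, match="closed"):
            tk.check_period(two_gene_tem, spec, (), 10)

    def test_period_links_delay_sums(self, two_gene_tem, two_gene_cycle):
        res = tk.check_period(
            two_gene_tem, two_gene_cycle, (), 10, init="zero", max_len=4
        )
        assert res.realizable
        # feasibility needs min sums below and max sums above the period
        assert res.region.entails(C("t_inc_min_x + t_dec_min_x <= 10"))
        assert res.region.entails(C("t_inc_max_x + t_dec_max_x >= 10"))

    def test_period_agrees_with_oracle(self, two_gene_tem, two_gene_cycle):
        res = tk.check_period(
            two_gene_tem, two_gene_cycle, (), 10, init="zero", max_len=4
        )
        obs = [tk.Observer("h_cycle_period", F(10), reset_at=0)]
        rng = random.Random(7)
        for _ in range(8):
            params = {}
            for v in two_gene_tem.components:
                for phase in "+-":
                    a, b = sorted([F(rng.randint(0, 8)), F(rng.randint(0, 8))])
                    params[tk.param_name(v, phase, "min")] = a
                    params[tk.param_name(v, phase, "max")] = b
            expected = tk.run_exists(
                two_gene_tem, params, two_gene_cycle, max_len=4, observers=obs
            ) is not None
            assert res.region.contains(params) == expected

    def test_zero_period_with_positive_min_is_empty(self, two_gene_tem, two_gene_cycle):
        res = tk.check_period(
            two_gene_tem, two_gene_cycle, (), 0, init="zero", max_len=4
        )
        # period 0 forces every guard's min delay on the cycle to zero
        if res.realizable:
            assert res.region.entails(C("t_inc_min_x = 0"))
            assert not res.region.contains(
                {**{p: F(0) for p in two_gene_tem.param_names()},
                 tk.param_name("x", "+", "min"): F(1),
                 tk.param_name("x", "+", "max"): F(1)}
            )


class TestPeakOrderings:
    def test_circadian_four_cycles(self, circadian_cycle):
        specs = tk.enumerate_peak_orderings(circadian_cycle, ("M_P", "M_T"))
        assert len(specs) == 4
        got = {tuple(tuple(sorted(dict(p).items())) for p in s.waypoints) for s in specs}

        def row(mids):
            wps = [
                {"M_P": "+", "M_T": "+"}, mids[0],
                {"M_P": "-", "M_T": "-"}, mids[1],
                {"M_P": "+", "M_T": "+"},
            ]
            return tuple(tuple(sorted(p.items())) for p in wps)

        table = {
            row(({"M_P": "+", "M_T": "-"}, {"M_P": "+", "M_T": "-"})),
            row(({"M_P": "-", "M_T": "+"}, {"M_P": "+", "M_T": "-"})),
            row(({"M_P": "+", "M_T": "-"}, {"M_P": "-", "M_T": "+"})),
            row(({"M_P": "-", "M_T": "+"}, {"M_P": "-", "M_T": "+"})),
        }
        assert got == table

    def test_degenerate_pair_rejected(self, circadian_cycle):
        with pytest.raises(ValueError):
            tk.enumerate_peak_orderings(circadian_cycle, ("M_P", "M_P"))

    def test_count_is_product_of_boundary_choices(self, two_gene_cycle):
        spec = tk.CycleSpec.of(
            [{"x": "+", "y": "+"}, {"x": "-", "y": "-"}, {"x": "+", "y": "+"}],
            closed=True,
        )
        assert len(tk.enumerate_peak_orderings(spec, ("x", "y"))) == 4


class TestTrimming:
    def test_trim_is_local(self, circadian_tem, circadian_anns):
        trimmed = tk.trim_tem(circadian_tem, circadian_anns)
        affected = {"C_N", "P_t", "T_t"}
        base = {e for e in circadian_tem.edges
                if not (e.flipped in affected
                        and e.direction(circadian_tem.components) == "high")}
        kept = {e for e in trimmed.edges
                if not (e.flipped in affected
                        and e.direction(trimmed.components) == "high")}
        assert base == kept  # untouched edges are bit-identical

    def test_trim_drops_contradicted_edges(self, circadian_tem, circadian_anns):
        trimmed = tk.trim_tem(circadian_tem, circadian_anns)
        for e in trimmed.edges:
            if e.flipped == "C_N" and e.direction(trimmed.components) == "high":
                assert trimmed.sign_of(e.source, "M_P") == "-"
                assert trimmed.sign_of(e.source, "M_T") == "-"
                assert len(e.guard) == 3  # base guard + two clock conditions

    def test_occurrence_annotations_cannot_be_static(self, circadian_tem):
        ann = tk.TimingAnnotation("C_N", "high", occurrence=1)
        with pytest.raises(ValueError):
            tk.trim_tem(circadian_tem, [ann])


class TestOccurrenceIndexedAnnotations:
    def test_second_occurrence_only(self):
        irs = IRS.of(["x"], interactions=[("x", "-", "x")])  # x flips forever
        tem = tk.build_tem(irs, ("+",))
        spec = tk.CycleSpec.of([{"x": "+"}, {"x": "+"}])
        # the second high peak of x must occur with clock exactly 4
        ann = tk.TimingAnnotation("x", "high", (C("h_x = 4"),), occurrence=2)
        res = tk.derive_parameter_region(tem, spec, [ann], init="zero", max_len=4)
        assert res.realizable
        params = generous_params(tem)
        w = tk.run_exists(tem, params, spec, [ann], max_len=4)
        assert w is not None
        assert tk.replay_witness(tem, params, w, [ann])


class TestIntervalFeasible:
    def test_detects_simple_emptiness(self):
        from temkit.linconstr import System

        sys = System.of([C("x >= 5"), C("x <= 3")])
        assert not interval_feasible(sys)

    def test_never_rejects_satisfiable(self):
        from temkit.linconstr import System

        rng = random.Random(3)
        for _ in range(30):
            cons = [
                Constraint.make(
                    {f"v{rng.randint(0, 2)}": rng.randint(-3, 3) or 1},
                    rng.choice(["<=", ">="]),
                    rng.randint(-5, 5),
                )
                for _ in range(4)
            ]
            sys = System.of(cons, ["v0", "v1", "v2"])
            if is_satisfiable(sys):
                assert interval_feasible(sys)


class TestInitialPoly:
    def test_symbolic_clocks_nonnegative(self, two_gene_tem):
        poly, clocks = initial_poly(two_gene_tem, "symbolic")
        assert clocks == {"h_x", "h_y"}
        assert implies(poly, C("h_x >= 0"))

    def test_concrete_initial_values(self, two_gene_tem):
        poly, _ = initial_poly(two_gene_tem, {"x": F(7), "y": F(12)})
        assert implies(poly, C("h_x = 7"))
        assert implies(poly, C("h_y = 12"))
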