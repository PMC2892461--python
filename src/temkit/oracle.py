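"""Concrete-parameter ground truth: bounded exhaustive run search.

Given concrete rational delay parameters, decides whether some run of the
automaton realizes a cycle specification (plus timing annotations and
observer clocks) within a bounded number of discrete steps.  The discrete
path is fixed and the dwell times in each location are solved for exactly as
one rational linear feasibility problem per (path, waypoint-realization)
branch -- delays are chosen existentially, matching the nondeterministic
interval semantics.  Used as the independent correctness oracle for the
symbolic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

from .linconstr import Constraint, System, is_satisfiable, sample_point
from .symbolic import (
    CycleSpec,
    Observer,
    TimingAnnotation,
    _applicable_annotations,
    _max_advance,
)
from .tem import TEM, Transition, clock_name, param_name, structural_constraints


class ParamError(ValueError):
    """Raised when a parameter assignment violates the structural constraints."""


def validate_params(tem: TEM, params: Mapping[str, Fraction]) -> dict[str, Fraction]:
    """Check completeness and ``0 <= min <= max`` per component and phase."""
    values: dict[str, Fraction] = {}
    for name in tem.param_names():
        if name not in params:
            raise ParamError(f"missing value for parameter {name}")
        values[name] = Fraction(params[name])
    for c in structural_constraints(tem):
        if not c.evaluate(values):
            raise ParamError(f"structural constraint violated: {c}")
    return values


@dataclass
class Witness:
    """A realizing schedule: the discrete path and one exact dwell per step."""

    edges: list[Transition]
    dwells: list[Fraction]

    def __len__(self) -> int:
        return len(self.edges)


_AffineExpr = tuple[dict[str, Fraction], Fraction]  # (dwell coeffs, constant)


def _le(lhs: _AffineExpr, rhs: Fraction, strict: bool = False) -> Constraint:
    return Constraint.make(lhs[0], "<" if strict else "<=", rhs - lhs[1])


def _clock_expr(
    arrival: dict[str, Fraction],
    last_reset: Mapping[str, dict[str, Fraction] | None],
    init: Mapping[str, Fraction],
    comp: str,
) -> _AffineExpr:
    """Value of h_comp at the current arrival/departure time, pre-reset."""
    reset = last_reset[comp]
    if reset is None:
        return dict(arrival), init[comp]
    coeffs = dict(arrival)
    for d, c in reset.items():
        coeffs[d] = coeffs.get(d, Fraction(0)) - c
        if coeffs[d] == 0:
            del coeffs[d]
    return coeffs, Fraction(0)


def run_exists(
    tem: TEM,
    params: Mapping[str, Fraction],
    spec: CycleSpec,
    annotations: Sequence[TimingAnnotation] = (),
    init: str | Mapping[str, Fraction] = "zero",
    max_len: int = 8,
    observers: Sequence[Observer] = (),
) -> Witness | None:
    """Does some run of <= ``max_len`` discrete steps realize the spec?

    Returns a witness schedule when one exists, else None.  Exact: per
    discrete path the dwell times form a rational linear system; infeasible
    prefixes are pruned by incremental satisfiability checks.
    """
    values = validate_params(tem, params)
    spec.validate(tem.components)
    comps = tem.components
    if init == "zero":
        init_clocks = {v: Fraction(0) for v in comps}
    elif init == "symbolic":
        raise ValueError("the concrete oracle needs a concrete initial valuation")
    else:
        init_clocks = {
            v: Fraction(init[v if v in init else clock_name(v)]) for v in comps
        }

    # invariant of the initial location at time zero
    for i, v in enumerate(comps):
        phase = tem.initial[i]
        if (v, phase) not in tem.infinite_max:
            if init_clocks[v] > values[param_name(v, phase, "max")]:
                return None

    nwp = len(spec.waypoints)
    outgoing = {loc: tem.outgoing(loc) for loc in tem.locations}

    def inv_at_departure(loc, arrival_T, last_reset, dwell_var) -> list[Constraint]:
        depart = dict(arrival_T)
        depart[dwell_var] = depart.get(dwell_var, Fraction(0)) + 1
        out = [Constraint.lower_bound(dwell_var, 0)]
        for i, v in enumerate(comps):
            phase = loc[i]
            if (v, phase) in tem.infinite_max:
                continue
            expr = _clock_expr(depart, last_reset, init_clocks, v)
            out.append(_le(expr, values[param_name(v, phase, "max")]))
        return out, depart

    def substitute_condition(c: Constraint, depart, last_reset) -> Constraint:
        coeffs: dict[str, Fraction] = {}
        const = c.const
        clock_of = {clock_name(v): v for v in comps}
        for var, a in c.coeffs:
            if var in clock_of:
                e_coeffs, e_const = _clock_expr(depart, last_reset, init_clocks, clock_of[var])
                for d, k in e_coeffs.items():
                    coeffs[d] = coeffs.get(d, Fraction(0)) + a * k
                const -= a * e_const
            elif var in values:
                const -= a * values[var]
            else:
                coeffs[var] = coeffs.get(var, Fraction(0)) + a
        return Constraint.make(coeffs, c.rel, const)

    result: list[Witness] = []

    def dfs(loc, wp_idx, depth, cons, arrival_T, last_reset, obs_reset, trace, path) -> bool:
        m = _max_advance(spec, wp_idx, loc, comps)
        for k in range(m + 1):
            idx2 = wp_idx + k
            obs2 = dict(obs_reset)
            for o in observers:
                if wp_idx <= o.reset_at < idx2:
                    obs2[o.name] = dict(arrival_T)
            if idx2 == nwp:
                final = list(cons)
                for o in observers:
                    start = obs2.get(o.name, {})
                    coeffs = dict(arrival_T)
                    for d, c in start.items():
                        coeffs[d] = coeffs.get(d, Fraction(0)) - c
                    final.append(Constraint.make(coeffs, "=", Fraction(o.final)))
                sys = System.of(final, {f"d{i}" for i in range(depth)})
                point = sample_point(sys)
                if point is not None:
                    dwells = [point.get(f"d{i}", Fraction(0)) for i in range(depth)]
                    result.append(Witness(list(path), dwells))
                    return True
                continue
            if depth == max_len:
                continue
            dwell = f"d{depth}"
            step_cons, depart = inv_at_departure(loc, arrival_T, last_reset, dwell)
            for e in outgoing[loc]:
                hits = _applicable_annotations(annotations, e, tem, trace)
                if hits is None:
                    continue
                i = comps.index(e.flipped)
                phase = loc[i]
                expr = _clock_expr(depart, last_reset, init_clocks, e.flipped)
                guard = Constraint.make(
                    {**{d: -c for d, c in expr[0].items()}}, "<=",
                    expr[1] - values[param_name(e.flipped, phase, "min")],
                )
                new_cons = cons + step_cons + [guard]
                for ann in hits:
                    for cond in ann.clock_conditions:
                        new_cons.append(substitute_condition(cond, depart, last_reset))
                sys = System.of(new_cons, {f"d{i}" for i in range(depth + 1)})
                if not is_satisfiable(sys):
                    continue
                reset2 = dict(last_reset)
                reset2[e.flipped] = depart
                path.append(e)
                done = dfs(e.target, idx2, depth + 1, new_cons, depart,
                           reset2, obs2, trace + (e.flipped,), path)
                path.pop()
                if done:
                    return True
        return False

    found = dfs(
        tem.initial, 0, 0, [], {}, {v: None for v in comps}, {}, (), []
    )
    return result[0] if found else None


def replay_witness(
    tem: TEM,
    params: Mapping[str, Fraction],
    witness: Witness,
    annotations: Sequence[TimingAnnotation] = (),
    init: Mapping[str, Fraction] | None = None,
) -> bool:
    """Re-execute a witness step by step in exact arithmetic.

    Verifies every invariant (at departure), guard and annotation clock
    condition along the schedule; independent of the feasibility encoding.
    """
    values = validate_params(tem, params)
    comps = tem.components
    clocks = {v: (init or {}).get(v, Fraction(0)) for v in comps}
    loc = tem.initial
    trace: tuple[str, ...] = ()
    for e, dwell in zip(witness.edges, witness.dwells):
        if e.source != loc or dwell < 0:
            return False
        for v in comps:
            clocks[v] += dwell
        for i, v in enumerate(comps):
            phase = loc[i]
            if (v, phase) not in tem.infinite_max:
                if clocks[v] > values[param_name(v, phase, "max")]:
                    return False
        valuation = {clock_name(v): clocks[v] for v in comps}
        valuation.update(values)
        for g in e.guard:
            if not g.evaluate(valuation):
                return False
        hits = _applicable_annotations(annotations, e, tem, trace)
        if hits is None:
            return False
        for ann in hits:
            for cond in ann.clock_conditions:
                if not cond.evaluate(valuation):
                    return False
        clocks[e.flipped] = Fraction(0)
        trace = trace + (e.flipped,)
        loc = e.target
    return True
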