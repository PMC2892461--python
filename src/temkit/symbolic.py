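"""Parametric symbolic reachability over a sign-state hybrid automaton.

A symbolic state couples a location with an exact rational polyhedron over
the clocks, any observer clocks, and all delay parameters.  Time elapse and
guarded discrete steps are polyhedral operators; projecting the clocks out
of the polyhedron of a state that has realized a qualitative cycle yields
one disjunct of the necessary parameter region.

The central function, :func:`derive_parameter_region`, explores all runs of
bounded discrete length that realize an ordered sequence of partial sign
patterns (waypoints joined by "eventually" hops), optionally trimmed by
timing annotations on designated peaks, and returns the union of the
parameter projections.  The result is exact for the bounded path set: a
parameter valuation satisfies the region iff some run within the bound
realizes the specification.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .linconstr import Constraint, Region, System, eliminate, is_satisfiable, subsumes
from .tem import (
    TEM,
    SignState,
    Transition,
    clock_name,
    param_name,
    structural_constraints,
)

# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

Pattern = tuple[tuple[str, str], ...]  # sorted ((component, sign), ...), partial


@dataclass(frozen=True)
class CycleSpec:
    """Ordered waypoint patterns; consecutive waypoints are joined by ->*.

    Each pattern constrains a subset of the components (the rest are
    wildcards).  ``closed`` records that the spec is a cycle (last waypoint
    pattern equals the first); it is required by period analysis.
    """

    waypoints: tuple[Pattern, ...]
    closed: bool = False

    @staticmethod
    def of(patterns: Sequence[Mapping[str, str]], closed: bool = False) -> "CycleSpec":
        wps = []
        for p in patterns:
            for comp, s in p.items():
                if s not in "+-":
                    raise ValueError(f"bad sign {s!r} for {comp!r}")
            wps.append(tuple(sorted(p.items())))
        if len(wps) < 2:
            raise ValueError("a cycle spec needs at least two waypoints")
        spec = CycleSpec(tuple(wps), closed)
        if closed and wps[0] != wps[-1]:
            raise ValueError("closed spec must end on its first waypoint pattern")
        return spec

    def validate(self, components: Sequence[str]) -> None:
        for p in self.waypoints:
            for comp, _ in p:
                if comp not in components:
                    raise ValueError(f"unknown component {comp!r} in cycle spec")


def pattern_matches(pattern: Pattern, location: SignState, components: Sequence[str]) -> bool:
    idx = {v: i for i, v in enumerate(components)}
    return all(location[idx[c]] == s for c, s in pattern)


@dataclass(frozen=True)
class TimingAnnotation:
    """Guard trimming for the peaks of one component.

    Applies to every discrete transition that is a ``direction`` peak of
    ``variable`` (or only to the ``occurrence``-th such peak along a run when
    an occurrence index is given).  ``sign_preconditions`` must hold in the
    source location, otherwise the annotated transition is infeasible;
    ``clock_conditions`` are conjoined to the guard and evaluated before the
    transition's resets.
    """

    variable: str
    direction: str  # "high" (+ -> -) or "low" (- -> +)
    clock_conditions: tuple[Constraint, ...] = ()
    sign_preconditions: tuple[tuple[str, str], ...] = ()
    occurrence: int | None = None  # 1-based along the run; None = all

    def __post_init__(self) -> None:
        if self.direction not in ("high", "low"):
            raise ValueError(f"bad peak direction {self.direction!r}")

    def matches_edge(self, edge: Transition, components: Sequence[str]) -> bool:
        return edge.flipped == self.variable and edge.direction(components) == self.direction

    def signs_hold(self, location: SignState, components: Sequence[str]) -> bool:
        return pattern_matches(tuple(sorted(self.sign_preconditions)), location, components)


@dataclass(frozen=True)
class Observer:
    """An auxiliary clock reset at a waypoint realization and pinned at the end.

    ``reset_at`` is the waypoint index whose realization resets the clock
    (the clock also starts at zero); ``final`` is the value the clock must
    have at the instant the last waypoint is realized.
    """

    name: str
    final: Fraction
    reset_at: int = 0


@dataclass(frozen=True)
class SymbolicState:
    """A reachability frontier element: location + exact polyhedron + trace."""

    location: SignState
    poly: System
    clocks: frozenset[str]  # component clocks plus observer clocks
    trace: tuple[str, ...] = ()
    wp_idx: int = 0


# ---------------------------------------------------------------------------
# Polyhedral operators
# ---------------------------------------------------------------------------

_ELAPSE = "_t_elapse"

# Below this universe size, per-step feasibility and state subsumption use the
# exact decision procedures; above it the search falls back to cheap sound
# approximations (interval propagation / syntactic inclusion).  Exactness of
# the final region is unaffected: projections are exact and unsatisfiable
# disjuncts are removed during simplification.
_EXACT_CHECK_MAX_VARS = 18


def _propagate_bounds(
    cons: Sequence[Constraint],
    lo: dict[str, Fraction],
    hi: dict[str, Fraction],
    max_rounds: int,
) -> bool:
    """One-sided interval tightening over ``cons``; mutates ``lo``/``hi``.

    Returns False when a variable's interval becomes empty (the system is
    certainly unsatisfiable); True means "possibly satisfiable".  Sound for
    any valid starting bounds, since tightening only shrinks intervals
    toward the true projection.  Strictness is ignored (closed relaxation).
    """
    lo_get, hi_get = lo.get, hi.get
    for _ in range(max_rounds):
        changed = False
        for c in cons:
            for sign in ((1,) if c.rel != "=" else (1, -1)):
                # sign * (sum a_i x_i) <= sign * const
                for var_j, a_j in c.coeffs:
                    aj = sign * a_j
                    total = 0
                    for var_i, a_i in c.coeffs:
                        if var_i is var_j:
                            continue
                        ai = sign * a_i
                        b = lo_get(var_i) if ai > 0 else hi_get(var_i)
                        if b is None:
                            total = None
                            break
                        total += ai * b
                    if total is None:
                        continue
                    bound = (sign * c.const - total) / aj
                    if aj > 0:
                        cur = hi_get(var_j)
                        if cur is None or bound < cur:
                            hi[var_j] = bound
                            changed = True
                            other = lo_get(var_j)
                            if other is not None and other > bound:
                                return False
                    else:
                        cur = lo_get(var_j)
                        if cur is None or bound > cur:
                            lo[var_j] = bound
                            changed = True
                            other = hi_get(var_j)
                            if other is not None and other < bound:
                                return False
        if not changed:
            break
    return True


_PRUNE_EPS = 1e-6  # conservative margin for the float pruning pre-filter


def _propagate_bounds_float(
    cons: Sequence[Constraint],
    lo: dict[str, float],
    hi: dict[str, float],
    max_rounds: int,
    memo: dict,
) -> bool:
    """Float shadow of :func:`_propagate_bounds`, used only as a pruning
    pre-filter by the path engine.

    Declares infeasibility only when an interval is empty by more than a
    conservative margin; branches that survive are verified exactly at
    projection time, so rounding can only cost pruning power on
    pathologically fine-grained inputs, never soundness of kept results.
    """
    lo_get, hi_get = lo.get, hi.get
    for _ in range(max_rounds):
        changed = False
        for c in cons:
            form = memo.get(c)
            if form is None:
                form = (
                    tuple((v, float(a)) for v, a in c.coeffs),
                    float(c.const),
                    (1.0,) if c.rel != "=" else (1.0, -1.0),
                )
                memo[c] = form
            coeffs, const, signs = form
            for sign in signs:
                for var_j, a_j in coeffs:
                    aj = sign * a_j
                    total = 0.0
                    for var_i, a_i in coeffs:
                        if var_i is var_j:
                            continue
                        ai = sign * a_i
                        b = lo_get(var_i) if ai > 0 else hi_get(var_i)
                        if b is None:
                            total = None
                            break
                        total += ai * b
                    if total is None:
                        continue
                    bound = (sign * const - total) / aj
                    if aj > 0:
                        cur = hi_get(var_j)
                        if cur is None or bound < cur - 1e-12:
                            hi[var_j] = bound
                            changed = True
                            other = lo_get(var_j)
                            if other is not None and other > bound + _PRUNE_EPS:
                                return False
                    else:
                        cur = lo_get(var_j)
                        if cur is None or bound > cur + 1e-12:
                            lo[var_j] = bound
                            changed = True
                            other = hi_get(var_j)
                            if other is not None and other < bound - _PRUNE_EPS:
                                return False
        if not changed:
            break
    return True


def interval_feasible(sys: System, max_rounds: int = 8) -> bool:
    """Cheap sound emptiness test by interval (bounds) propagation.

    Returns False only when the system is certainly empty; True means
    "possibly satisfiable".
    """
    if sys.is_false:
        return False
    return _propagate_bounds(sys.constraints, {}, {}, max_rounds)


def _maybe_satisfiable(sys: System) -> bool:
    """Exact when small, interval propagation otherwise (sound either way)."""
    if len(sys.universe) <= _EXACT_CHECK_MAX_VARS:
        return is_satisfiable(sys)
    return interval_feasible(sys)


def time_elapse(state: SymbolicState, tem: TEM) -> SymbolicState:
    """Let time pass: all clocks advance by a common t >= 0 inside the invariant.

    Exact: the elapse amount is projected away.  Returns a state with an
    unsatisfiable polyhedron when the invariant is already violated.
    """
    poly, clocks = state.poly, state.clocks
    cons = []
    for c in poly.constraints:
        shift = sum((coef for v, coef in c.coeffs if v in clocks), Fraction(0))
        if shift:
            d = dict(c.coeffs)
            d[_ELAPSE] = d.get(_ELAPSE, Fraction(0)) - shift
            cons.append(Constraint.make(d, c.rel, c.const))
        else:
            cons.append(c)
    cons.append(Constraint.lower_bound(_ELAPSE, 0))
    sys = System.of(cons, poly.universe | {_ELAPSE})
    sys = sys.conjoin(tem.invariant(state.location))
    out = eliminate(sys, {_ELAPSE})
    return SymbolicState(state.location, out, clocks, state.trace, state.wp_idx)


def _applicable_annotations(
    annotations: Iterable[TimingAnnotation],
    edge: Transition,
    tem: TEM,
    trace: tuple[str, ...],
) -> list[TimingAnnotation] | None:
    """Annotations applying to this firing; None when a sign precondition fails."""
    hits = []
    for ann in annotations:
        if not ann.matches_edge(edge, tem.components):
            continue
        if ann.occurrence is not None:
            prior = _peak_count(tem, trace, edge.source, ann.variable, ann.direction)
            if prior + 1 != ann.occurrence:
                continue
        if not ann.signs_hold(edge.source, tem.components):
            return None
        hits.append(ann)
    return hits


def _peak_count(tem: TEM, trace: tuple[str, ...], current: SignState,
                variable: str, direction: str) -> int:
    """How many (variable, direction) peaks occurred along the trace so far."""
    # replay signs backwards from the current location
    i = tem.components.index(variable)
    sign = current[i]
    count = 0
    for flipped in reversed(trace):
        if flipped == variable:
            prev = "-" if sign == "+" else "+"
            if (prev == "+" and direction == "high") or (prev == "-" and direction == "low"):
                count += 1
            sign = prev
    return count


def discrete_step(
    state: SymbolicState,
    edge: Transition,
    tem: TEM,
    annotations: Sequence[TimingAnnotation] = (),
    exact: bool = True,
) -> SymbolicState:
    """Fire a guarded edge: guard + annotations, resets, target invariant.

    Annotation clock conditions are evaluated before the resets; sign
    preconditions are checked against the source location.  Returns a state
    with an unsatisfiable polyhedron when the step is infeasible.  With
    ``exact=False`` the final emptiness check is the cheap sound
    approximation (used internally by the bounded search, which restores
    exactness at projection time).
    """
    if edge.source != state.location:
        raise ValueError("edge does not start at the state's location")
    hits = _applicable_annotations(annotations, edge, tem, state.trace)
    clocks = state.clocks
    if hits is None:
        return SymbolicState(edge.target, _unsat(state.poly), clocks, state.trace, state.wp_idx)
    cons = list(edge.guard)
    for ann in hits:
        cons.extend(ann.clock_conditions)
    poly = state.poly.conjoin(cons)
    if poly.is_false:
        return SymbolicState(edge.target, _unsat(poly), clocks, state.trace, state.wp_idx)
    poly = eliminate(poly, set(edge.resets))
    poly = poly.conjoin(
        [Constraint.equality(h, 0) for h in edge.resets]
    ).with_universe(edge.resets)
    poly = poly.conjoin(tem.invariant(edge.target))
    empty = not is_satisfiable(poly) if exact else not _maybe_satisfiable(poly)
    if empty:
        poly = _unsat(poly)
    return SymbolicState(
        edge.target, poly, clocks, state.trace + (edge.flipped,), state.wp_idx
    )


def _unsat(like: System) -> System:
    return System.of([Constraint.make({}, "<", 0)], like.universe)


def reset_clock(poly: System, name: str) -> System:
    """Project a clock away and pin it at zero (used for observer resets)."""
    out = eliminate(poly, {name})
    return out.conjoin([Constraint.equality(name, 0)]).with_universe({name})


# ---------------------------------------------------------------------------
# Discrete-only waypoint matching (used by tests and by the concrete oracle)
# ---------------------------------------------------------------------------

def _max_advance(spec: CycleSpec, wp_idx: int, location: SignState,
                 components: Sequence[str]) -> int:
    """Largest k such that waypoints wp_idx .. wp_idx+k-1 all match here."""
    k = 0
    while wp_idx + k < len(spec.waypoints) and pattern_matches(
        spec.waypoints[wp_idx + k], location, components
    ):
        k += 1
    return k


def match_paths(tem: TEM, spec: CycleSpec, max_len: int) -> list[list[Transition]]:
    """All edge sequences of length <= max_len from the initial location that
    realize the waypoint patterns in order (empty ->* hops allowed).

    Purely discrete -- guards and parameters are ignored.  A path is reported
    at the moment the final waypoint is realized and is not extended further.
    """
    spec.validate(tem.components)
    if max_len < 0:
        raise ValueError("max_len must be nonnegative")
    nwp = len(spec.waypoints)
    out: list[list[Transition]] = []
    outgoing = {loc: tem.outgoing(loc) for loc in tem.locations}

    def dfs(loc: SignState, wp_idx: int, path: list[Transition]) -> None:
        wp_idx += _max_advance(spec, wp_idx, loc, tem.components)
        if wp_idx == nwp:
            out.append(list(path))
            return
        if len(path) == max_len:
            return
        for e in outgoing[loc]:
            path.append(e)
            dfs(e.target, wp_idx, path)
            path.pop()

    dfs(tem.initial, 0, [])
    return out


# ---------------------------------------------------------------------------
# Region derivation
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    """Outcome of a bounded parametric reachability analysis."""

    region: Region
    max_len: int
    n_paths: int  # number of realizing (path, realization) branches found
    realizable: bool = field(init=False)

    def __post_init__(self) -> None:
        self.realizable = self.n_paths > 0


def initial_poly(
    tem: TEM,
    init: str | Mapping[str, Fraction] = "symbolic",
    observers: Sequence[Observer] = (),
) -> tuple[System, frozenset[str]]:
    """Initial polyhedron: clocks per ``init``, observers at zero, and the
    initial location's invariant (structural parameter constraints are
    conjoined later, at projection time)."""
    clocks = set(tem.clocks) | {o.name for o in observers}
    cons: list[Constraint] = []
    for comp in tem.components:
        h = clock_name(comp)
        if init == "symbolic":
            cons.append(Constraint.lower_bound(h, 0))
        elif init == "zero":
            cons.append(Constraint.equality(h, 0))
        else:
            key = comp if comp in init else h
            cons.append(Constraint.equality(h, Fraction(init[key])))
    for o in observers:
        cons.append(Constraint.equality(o.name, 0))
    universe = clocks | set(tem.param_names())
    sys = System.of(cons, universe).conjoin(tem.invariant(tem.initial))
    return sys, frozenset(clocks)


def derive_parameter_region(
    tem: TEM,
    spec: CycleSpec,
    annotations: Sequence[TimingAnnotation] = (),
    init: str | Mapping[str, Fraction] = "symbolic",
    max_len: int | None = None,
    observers: Sequence[Observer] = (),
    subsumption: bool = True,
    simplify: bool = True,
    engine: str = "auto",
) -> AnalysisResult:
    """Necessary parameter constraints for the bounded realization of ``spec``.

    Explores every run of at most ``max_len`` discrete steps from the initial
    location.  Waypoints are realized at location arrival instants; every
    realization assignment is enumerated (a waypoint may be realized at the
    same location as its predecessor).  Observer clocks are reset at the
    realization of their designated waypoint and pinned to their final value
    at the realization of the last waypoint.

    The returned region is the simplified union, over all realizing branches,
    of the exact projection of the final polyhedron onto the parameters,
    conjoined (by construction of the initial polyhedron) with the structural
    constraints.  Symbolic states subsumed by an earlier state at the same
    location with the same waypoint progress are pruned; this never loses
    parameter valuations.
    """
    spec.validate(tem.components)
    if max_len is None:
        max_len = len(spec.waypoints) - 1 + 2 * tem.n
    nwp = len(spec.waypoints)
    for o in observers:
        if not 0 <= o.reset_at < nwp:
            raise ValueError(f"observer {o.name} resets at waypoint {o.reset_at}, out of range")
    counted = [a for a in annotations if a.occurrence is not None]
    params = frozenset(tem.param_names())
    struct = structural_constraints(tem)
    poly0, clockset = initial_poly(tem, init, observers)
    small = len(poly0.universe) <= _EXACT_CHECK_MAX_VARS
    if engine not in ("auto", "zone", "path"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "path" or (engine == "auto" and not small):
        # large models: per-path dwell-time encoding avoids zone blowup
        disjuncts, n_hits = _search_dwell_encoding(
            tem, spec, annotations, init, max_len, observers
        )
        region = Region(disjuncts, params)
        if simplify:
            region = region.simplify()
        return AnalysisResult(region, max_len, n_hits)
    disjuncts: list[System] = []
    n_hits = 0
    visited: dict[tuple, list] = {}
    outgoing = {loc: tem.outgoing(loc) for loc in tem.locations}

    start = SymbolicState(tem.initial, poly0, clockset)
    if not is_satisfiable(poly0.conjoin(struct)):
        return AnalysisResult(Region.empty(params), max_len, 0)
    queue: deque[tuple[SymbolicState, int]] = deque([(start, 0)])

    def subsumed(key: tuple, poly: System) -> bool:
        """Prune states covered by an earlier state with the same progress."""
        olds = visited.setdefault(key, [])
        if small:
            if any(subsumes(poly, old) for old in olds):
                return True
            olds.append(poly)
        else:
            # syntactic sufficient condition: a superset of constraints
            # denotes a subset of points
            cset = frozenset(poly.constraints)
            if any(old <= cset for old in olds):
                return True
            olds.append(cset)
        return False

    while queue:
        state, depth = queue.popleft()
        m = _max_advance(spec, state.wp_idx, state.location, tem.components)
        for k in range(m + 1):
            idx2 = state.wp_idx + k
            poly2 = state.poly
            for o in observers:
                if state.wp_idx <= o.reset_at < idx2:
                    poly2 = reset_clock(poly2, o.name)
            if idx2 == nwp:
                for o in observers:
                    poly2 = poly2.conjoin([Constraint.equality(o.name, Fraction(o.final))])
                proj = eliminate(poly2, clockset).conjoin(struct)
                if is_satisfiable(proj):
                    n_hits += 1
                    disjuncts.append(proj)
                continue
            key = (state.location, idx2)
            if counted:
                key = key + tuple(
                    _peak_count(tem, state.trace, state.location, a.variable, a.direction)
                    for a in counted
                )
            branch = SymbolicState(state.location, poly2, clockset, state.trace, idx2)
            if subsumption and subsumed(key, poly2):
                continue
            if depth >= max_len:
                continue
            elapsed = time_elapse(branch, tem)
            if elapsed.poly.is_false or not _maybe_satisfiable(elapsed.poly):
                continue
            for e in outgoing[state.location]:
                nxt = discrete_step(elapsed, e, tem, annotations, exact=small)
                if not nxt.poly.is_false:
                    queue.append((SymbolicState(
                        nxt.location, nxt.poly, clockset, nxt.trace, idx2
                    ), depth + 1))

    region = Region(disjuncts, params)
    if simplify:
        region = region.simplify()
    return AnalysisResult(region, max_len, n_hits)


def _search_dwell_encoding(
    tem: TEM,
    spec: CycleSpec,
    annotations: Sequence[TimingAnnotation],
    init: str | Mapping[str, Fraction],
    max_len: int,
    observers: Sequence[Observer],
) -> tuple[list[System], int]:
    """Path-encoded exploration for large models.

    Instead of propagating a clock-zone polyhedron (whose time-elapse
    projections blow up with depth), each branch carries its constraints
    over per-step dwell-time variables ``d0..dk`` (plus symbolic initial
    clock offsets for a symbolic start); clocks are affine expressions in
    these.  Nothing is projected until a branch realizes the full spec, at
    which point the dwells/offsets are eliminated in one exact shot.
    Produces the same parameter region as the zone engine.
    """
    comps = tem.components
    nwp = len(spec.waypoints)
    struct = structural_constraints(tem)
    outgoing = {loc: tem.outgoing(loc) for loc in tem.locations}
    clock_of = {clock_name(v): v for v in comps}
    obs_names = {o.name for o in observers}

    # initial clock offsets: exact rationals, or fresh nonnegative symbols
    offsets: dict[str, tuple[dict[str, int], Fraction]] = {}
    base_cons: list[Constraint] = list(struct)
    aux_vars: set[str] = set()
    for v in comps:
        if init == "zero":
            offsets[v] = ({}, Fraction(0))
        elif init == "symbolic":
            ov = f"_h0_{v}"
            aux_vars.add(ov)
            offsets[v] = ({ov: 1}, Fraction(0))
            base_cons.append(Constraint.lower_bound(ov, 0))
        else:
            key = v if v in init else clock_name(v)
            offsets[v] = ({}, Fraction(init[key]))

    def clock_at(time_expr: dict[str, int], reset, comp: str):
        """(coeffs, const) of h_comp at the given absolute-time expression."""
        if reset is None:
            off_c, off_k = offsets[comp]
            coeffs = dict(time_expr)
            for var, c in off_c.items():
                coeffs[var] = coeffs.get(var, 0) + c
            return coeffs, off_k
        coeffs = dict(time_expr)
        for var, c in reset.items():
            coeffs[var] = coeffs.get(var, 0) - c
            if coeffs[var] == 0:
                del coeffs[var]
        return coeffs, Fraction(0)

    def invariant_cons(loc: SignState, time_expr, last_reset) -> list[Constraint]:
        out = []
        for i, v in enumerate(comps):
            phase = loc[i]
            if (v, phase) in tem.infinite_max:
                continue
            coeffs, k0 = clock_at(time_expr, last_reset[v], v)
            coeffs = dict(coeffs)
            coeffs[param_name(v, phase, "max")] = coeffs.get(
                param_name(v, phase, "max"), 0) - 1
            out.append(Constraint.make(coeffs, "<=", -k0))
        return out

    def rewrite_condition(c: Constraint, time_expr, last_reset) -> Constraint:
        coeffs: dict[str, Fraction] = {}
        const = c.const
        for var, a in c.coeffs:
            if var in clock_of:
                comp = clock_of[var]
                e_coeffs, e_const = clock_at(time_expr, last_reset[comp], comp)
                for d, k in e_coeffs.items():
                    coeffs[d] = coeffs.get(d, 0) + a * k
                const -= a * e_const
            else:
                coeffs[var] = coeffs.get(var, 0) + a
        return Constraint.make(coeffs, c.rel, const)

    disjuncts: list[System] = []
    seen_projections: set = set()
    n_hits = 0

    # initial-location invariant at time zero
    init_reset = {v: None for v in comps}
    base_cons.extend(invariant_cons(tem.initial, {}, init_reset))
    for c in base_cons:
        if c.is_ground and not c.ground_truth():
            return [], 0
    memo: dict = {}
    lo0: dict[str, float] = {}
    hi0: dict[str, float] = {}
    if not _propagate_bounds_float(base_cons, lo0, hi0, 4, memo):
        return [], 0

    stack = [(tem.initial, 0, 0, base_cons, {}, init_reset, {}, (), lo0, hi0)]
    while stack:
        (loc, wp_idx, depth, cons, arrival, last_reset, obs_reset, trace,
         lo, hi) = stack.pop()
        m = _max_advance(spec, wp_idx, loc, comps)
        for k in range(m + 1):
            idx2 = wp_idx + k
            obs2 = dict(obs_reset)
            for o in observers:
                if wp_idx <= o.reset_at < idx2:
                    obs2[o.name] = dict(arrival)
            if idx2 == nwp:
                # open phase windows are bounded by their value at this
                # (final) instant; earlier departures are implied
                final = cons + invariant_cons(loc, arrival, last_reset)
                for o in observers:
                    coeffs = dict(arrival)
                    for d, c in obs2.get(o.name, {}).items():
                        coeffs[d] = coeffs.get(d, 0) - c
                    final.append(Constraint.make(coeffs, "=", Fraction(o.final)))
                dwells = {f"_d{i}" for i in range(depth)}
                if not _propagate_bounds_float(final, dict(lo), dict(hi), 3, memo):
                    continue
                sys = System.of(final, dwells | aux_vars | set(tem.param_names()))
                if sys.is_false:
                    continue
                proj = eliminate(sys, dwells | aux_vars)
                key = proj.canonical()
                if key in seen_projections:
                    n_hits += 1
                    continue
                seen_projections.add(key)
                if is_satisfiable(proj):
                    n_hits += 1
                    disjuncts.append(proj)
                continue
            if depth >= max_len:
                continue
            dwell = f"_d{depth}"
            depart = dict(arrival)
            depart[dwell] = depart.get(dwell, 0) + 1
            # departure invariants: used for pruning every step, but only the
            # flipped component's (its window closes here) is kept permanently
            # -- within a window the latest instant implies all earlier ones
            step_inv = invariant_cons(loc, depart, last_reset)
            step_cons = [Constraint.lower_bound(dwell, 0)]
            inv_of = {}
            for c in step_inv:
                for v, _ in c.coeffs:
                    if v.startswith("t_"):
                        inv_of[v] = c
            for e in outgoing[loc]:
                hits = _applicable_annotations(annotations, e, tem, trace)
                if hits is None:
                    continue
                i = comps.index(e.flipped)
                coeffs, k0 = clock_at(depart, last_reset[e.flipped], e.flipped)
                gcoeffs = {d: -c for d, c in coeffs.items()}
                phase = loc[i]
                tmin = param_name(e.flipped, phase, "min")
                gcoeffs[tmin] = gcoeffs.get(tmin, 0) + 1
                added = step_cons + [Constraint.make(gcoeffs, "<=", k0)]
                closing = inv_of.get(param_name(e.flipped, phase, "max"))
                if closing is not None:
                    added.append(closing)
                for ann in hits:
                    for cond in ann.clock_conditions:
                        added.append(rewrite_condition(cond, depart, last_reset))
                if any(c.is_ground and not c.ground_truth() for c in added):
                    continue
                new_cons = cons + added
                # warm-started bound tightening: parent bounds stay valid
                lo2, hi2 = dict(lo), dict(hi)
                if not _propagate_bounds_float(added + step_inv, lo2, hi2, 1, memo):
                    continue
                if not _propagate_bounds_float(new_cons + step_inv, lo2, hi2, 2, memo):
                    continue
                reset2 = dict(last_reset)
                reset2[e.flipped] = depart
                stack.append((e.target, idx2, depth + 1, new_cons, depart,
                              reset2, obs2, trace + (e.flipped,), lo2, hi2))
    return disjuncts, n_hits


def check_period(
    tem: TEM,
    spec: CycleSpec,
    annotations: Sequence[TimingAnnotation],
    period_value,
    **kwargs,
) -> AnalysisResult:
    """Impose a total cycle duration via an observer clock.

    The observer is reset at the realization of the first waypoint, never
    reset elsewhere, and must equal ``period_value`` at cycle closure.
    Requires a closed spec.
    """
    if not spec.closed:
        raise ValueError("period analysis requires a closed cycle spec")
    obs = Observer("h_cycle_period", Fraction(period_value), reset_at=0)
    observers = tuple(kwargs.pop("observers", ())) + (obs,)
    return derive_parameter_region(tem, spec, annotations, observers=observers, **kwargs)


def enumerate_peak_orderings(spec: CycleSpec, variables: tuple[str, str]) -> list[CycleSpec]:
    """Refine a two-phase cycle by ordering the peaks of two components.

    From an elementary closed cycle ``w0 ->* w1 ->* w0`` in which both
    components are constrained (and flip sign between the two phases),
    produce the four specs obtained by inserting, at each phase boundary, an
    intermediate waypoint where exactly one of the two has already flipped.
    Output order: product of (first variable flips first | second flips
    first) over the two boundaries.
    """
    a, b = variables
    if a == b:
        raise ValueError("need two distinct components")
    if len(spec.waypoints) != 3:
        raise ValueError("expected an elementary three-waypoint cycle")
    w0, w1, w2 = (dict(p) for p in spec.waypoints)
    for w in (w0, w1):
        for v in variables:
            if v not in w:
                raise ValueError(f"{v!r} not constrained in every phase waypoint")
    out = []
    for first1 in (a, b):
        mid1 = {v: (w1[v] if v == first1 else w0[v]) for v in variables}
        for first2 in (a, b):
            mid2 = {v: (w2[v] if v == first2 else w1[v]) for v in variables}
            out.append(
                CycleSpec.of(
                    [dict(spec.waypoints[0]), mid1, dict(spec.waypoints[1]),
                     mid2, dict(spec.waypoints[2])],
                    closed=spec.closed,
                )
            )
    return out


def trim_tem(tem: TEM, annotations: Sequence[TimingAnnotation]) -> TEM:
    """Statically strengthen guards with annotation conditions (for export).

    Only occurrence-free annotations can be applied statically; edges whose
    source contradicts a sign precondition are removed.
    """
    for a in annotations:
        if a.occurrence is not None:
            raise ValueError("occurrence-indexed annotations cannot be trimmed statically")
    edges = []
    for e in tem.edges:
        guard = list(e.guard)
        keep = True
        for a in annotations:
            if not a.matches_edge(e, tem.components):
                continue
            if not a.signs_hold(e.source, tem.components):
                keep = False
                break
            guard.extend(a.clock_conditions)
        if keep:
            edges.append(Transition(e.source, e.target, e.flipped,
                                    tuple(guard), e.resets, e.rules))
    return TEM(tem.irs, tem.initial, tuple(edges), tem.infinite_max)
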