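"""Temporal evolution models: sign-tuple hybrid automata built from an IRS.

A location is a tuple of derivative signs, one per component.  Each component
``x`` owns one clock ``h_x`` and four delay parameters bounding the time the
component may spend increasing or decreasing::

    t_inc_min_x <= (duration of a + phase) <= t_inc_max_x
    t_dec_min_x <= (duration of a - phase) <= t_dec_max_x

A max bound may be declared infinite, in which case the corresponding
invariant conjunct is simply omitted (the equilibrium abstraction: a phase
that may last forever).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from fractions import Fraction

from .irs import IRS, parse_irs, write_irs
from .linconstr import Constraint

Sign = str  # "+" or "-"
SignState = tuple[Sign, ...]

RULE_R_TARGET = "R-target"
RULE_R_SOURCE = "R-source"
RULE_I_POS = "I-pos"
RULE_I_NEG = "I-neg"

_PHASE_WORD = {"+": "inc", "-": "dec"}


def clock_name(component: str) -> str:
    return f"h_{component}"


def param_name(component: str, phase: Sign, bound: str) -> str:
    if phase not in _PHASE_WORD or bound not in ("min", "max"):
        raise ValueError(f"bad delay parameter ({component}, {phase}, {bound})")
    return f"t_{_PHASE_WORD[phase]}_{bound}_{component}"


@dataclass(frozen=True)
class DelayParam:
    """One of the four delay-interval bounds of a component's phase."""

    component: str
    phase: Sign  # phase whose duration is bounded
    bound: str  # "min" or "max"

    @property
    def name(self) -> str:
        return param_name(self.component, self.phase, self.bound)


def sign_state_str(state: SignState) -> str:
    return "(" + ",".join(state) + ")"


def enumerate_locations(n: int) -> list[SignState]:
    """All 2**n sign tuples in lexicographic order with ``+`` before ``-``."""
    if n < 1:
        raise ValueError("need at least one variable")
    return [tuple(t) for t in itertools.product("+-", repeat=n)]


def applicable_flips(irs: IRS, location: SignState) -> set[tuple[str, str]]:
    """Components that may switch sign in ``location``, with the rule tags.

    Transition rules (one flip per transition):

    * ``R-target``: a reaction ``(x_i, x_j)`` with ``s_i != s_j`` flips x_j.
    * ``R-source``: a reaction ``(x_i, x_j)`` with ``s_i = +`` flips x_i.
    * ``I-pos``: an interaction ``(x_i, +, x_j)`` with ``s_i != s_j`` flips
      x_j (vacuous for positive auto-regulations, which are inert).
    * ``I-neg``: an interaction ``(x_i, -, x_j)`` with ``s_i = s_j`` flips x_j.
    """
    if len(location) != irs.n:
        raise ValueError("location arity does not match the IRS")
    sign = {v: location[i] for i, v in enumerate(irs.components)}
    flips: set[tuple[str, str]] = set()
    for src, tgt in irs.reactions:
        if sign[src] != sign[tgt]:
            flips.add((tgt, RULE_R_TARGET))
        if sign[src] == "+":
            flips.add((src, RULE_R_SOURCE))
    for src, a, tgt in irs.interactions:
        if a == "+" and sign[src] != sign[tgt]:
            flips.add((tgt, RULE_I_POS))
        elif a == "-" and sign[src] == sign[tgt]:
            flips.add((tgt, RULE_I_NEG))
    return flips


def _flip(state: SignState, index: int) -> SignState:
    out = list(state)
    out[index] = "-" if out[index] == "+" else "+"
    return tuple(out)


@dataclass(frozen=True)
class Transition:
    """A guarded, clock-resetting edge flipping exactly one component."""

    source: SignState
    target: SignState
    flipped: str
    guard: tuple[Constraint, ...]
    resets: tuple[str, ...]
    rules: frozenset[str] = field(default_factory=frozenset)

    def direction(self, components: tuple[str, ...]) -> str:
        """``high`` for a + -> - flip (concentration maximum), else ``low``."""
        i = components.index(self.flipped)
        return "high" if self.source[i] == "+" else "low"


@dataclass(frozen=True)
class TEM:
    """A complete sign-state hybrid automaton over an IRS."""

    irs: IRS
    initial: SignState
    edges: tuple[Transition, ...]
    infinite_max: frozenset[tuple[str, Sign]] = field(default_factory=frozenset)

    @property
    def components(self) -> tuple[str, ...]:
        return self.irs.components

    @property
    def n(self) -> int:
        return self.irs.n

    @property
    def locations(self) -> list[SignState]:
        return enumerate_locations(self.n)

    @property
    def clocks(self) -> tuple[str, ...]:
        return tuple(clock_name(v) for v in self.components)

    def delay_params(self) -> list[DelayParam]:
        return [
            DelayParam(v, phase, bound)
            for v in self.components
            for phase in "+-"
            for bound in ("min", "max")
            if not (bound == "max" and (v, phase) in self.infinite_max)
        ]

    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.delay_params())

    def invariant(self, location: SignState) -> list[Constraint]:
        """``h_x <= t_{sign(x)}_max_x`` per component, omitting infinite maxima."""
        out = []
        for i, v in enumerate(self.components):
            phase = location[i]
            if (v, phase) in self.infinite_max:
                continue
            out.append(
                Constraint.make(
                    {clock_name(v): 1, param_name(v, phase, "max"): -1}, "<=", 0
                )
            )
        return out

    def outgoing(self, location: SignState) -> list[Transition]:
        return [e for e in self.edges if e.source == location]

    def sign_of(self, location: SignState, component: str) -> Sign:
        return location[self.components.index(component)]

    def to_dict(self) -> dict:
        return {
            "irs": write_irs(self.irs),
            "components": list(self.components),
            "initial": "".join(self.initial),
            "infinite_max": sorted(f"{v}{p}" for v, p in self.infinite_max),
            "n_locations": 2 ** self.n,
            "clocks": list(self.clocks),
            "parameters": list(self.param_names()),
            "edges": [
                {
                    "source": "".join(e.source),
                    "target": "".join(e.target),
                    "flipped": e.flipped,
                    "rules": sorted(e.rules),
                    "guard": [str(g) for g in e.guard],
                    "resets": list(e.resets),
                }
                for e in self.edges
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def build_tem(
    irs: IRS,
    initial: SignState | None = None,
    infinite_max: frozenset[tuple[str, Sign]] | set = frozenset(),
) -> TEM:
    """Construct the full automaton from an IRS by the four flip rules.

    For each location and each applicable flip of component ``x`` in phase
    ``s`` there is exactly one edge with guard ``h_x >= t_{s}_min_x`` and
    reset ``{h_x}``; distinct rules justifying the same flip collapse onto
    that single edge (the edge set is a set) with all rule tags retained.
    """
    infinite_max = frozenset(infinite_max)
    for v, p in infinite_max:
        if v not in irs.components or p not in "+-":
            raise ValueError(f"bad infinite-max entry ({v!r}, {p!r})")
    locations = enumerate_locations(irs.n)
    if initial is None:
        initial = locations[0]
    initial = tuple(initial)
    if len(initial) != irs.n or any(s not in "+-" for s in initial):
        raise ValueError(f"invalid initial location {initial!r}")
    index = {v: i for i, v in enumerate(irs.components)}
    edges: list[Transition] = []
    for loc in locations:
        by_component: dict[str, set[str]] = {}
        for comp, rule in applicable_flips(irs, loc):
            by_component.setdefault(comp, set()).add(rule)
        for comp in sorted(by_component, key=lambda v: index[v]):
            i = index[comp]
            phase = loc[i]
            guard = Constraint.make(
                {clock_name(comp): 1, param_name(comp, phase, "min"): -1}, ">=", 0
            )
            edges.append(
                Transition(
                    source=loc,
                    target=_flip(loc, i),
                    flipped=comp,
                    guard=(guard,),
                    resets=(clock_name(comp),),
                    rules=frozenset(by_component[comp]),
                )
            )
    return TEM(irs, initial, tuple(edges), infinite_max)


def tem_from_dict(data: dict) -> TEM:
    """Rebuild a TEM from its dump (reconstructs deterministically from the IRS)."""
    irs = parse_irs(data["irs"])
    initial = tuple(data["initial"])
    infinite = frozenset((s[:-1], s[-1]) for s in data.get("infinite_max", ()))
    tem = build_tem(irs, initial, infinite)
    if len(tem.edges) != len(data["edges"]):
        raise ValueError("TEM dump is inconsistent with its IRS")
    return tem


def structural_constraints(tem: TEM) -> list[Constraint]:
    """``0 <= t_{a}_min_x`` and ``t_{a}_min_x <= t_{a}_max_x`` per phase.

    The ordering constraint is omitted for phases whose max bound is
    infinite.  Conjoined to every downstream analysis.
    """
    out: list[Constraint] = []
    for v in tem.components:
        for phase in "+-":
            tmin = param_name(v, phase, "min")
            out.append(Constraint.make({tmin: 1}, ">=", 0))
            if (v, phase) not in tem.infinite_max:
                tmax = param_name(v, phase, "max")
                out.append(Constraint.make({tmin: 1, tmax: -1}, "<=", 0))
    return out
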