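"""Exact rational linear constraints, Fourier-Motzkin projection and regions.

All arithmetic is exact; no floating point anywhere.  Internally a
constraint is canonicalized to integer coefficients with gcd 1 (the constant
term may remain a rational), which keeps hashing and the pairwise
Fourier-Motzkin combinations fast.  The public constraint language is closed
(``<=``, ``=``, ``>=``), matching the guard/invariant language of the hybrid
models built elsewhere in this package; strict inequalities exist internally
so that entailment and redundancy checks can reason about complements of
closed constraints exactly.

A :class:`System` is a finite conjunction over a declared variable universe;
a :class:`Region` is a finite disjunction of systems (the parameter-space
output of the reachability analysis).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

Rat = Fraction

_REL_FLIP = {">=": "<=", ">": "<"}
_ALL_RELS = ("<=", "<", "=", ">=", ">")


def _as_rat(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        raise TypeError(f"floating point value {x!r} not allowed; use Fraction")
    return Fraction(x)


class Constraint:
    """A linear constraint ``sum(coeff_i * var_i) rel const``.

    Canonical form: ``rel`` in ``{<=, <, =}``; coefficients are a sorted
    tuple of ``(var, int)`` pairs with gcd 1 and zeros dropped (equalities
    additionally have a positive leading coefficient); the constant is a
    :class:`fractions.Fraction`.  Instances are immutable and hashable.
    Ground constraints (no variables) are permitted and evaluate to a truth
    value.  Use :meth:`make` -- the raw constructor assumes canonical input.
    """

    __slots__ = ("coeffs", "rel", "const", "_map", "_hash")

    def __init__(self, coeffs: tuple[tuple[str, int], ...], rel: str, const: Fraction):
        self.coeffs = coeffs
        self.rel = rel
        self.const = const
        self._map = dict(coeffs)
        self._hash = hash((coeffs, rel, const))

    @staticmethod
    def make(coeffs: Mapping[str, Fraction | int], rel: str, const) -> "Constraint":
        if rel not in _ALL_RELS:
            raise ValueError(f"unknown relation {rel!r}")
        cs = {v: _as_rat(c) for v, c in coeffs.items() if c != 0}
        b = _as_rat(const)
        if rel in _REL_FLIP:
            cs = {v: -c for v, c in cs.items()}
            b = -b
            rel = _REL_FLIP[rel]
        items = sorted(cs.items())
        if items:
            scale = math.lcm(*(c.denominator for _, c in items))
            ints = [(v, int(c * scale)) for v, c in items]
            g = math.gcd(*(abs(c) for _, c in ints))
            if rel == "=" and ints[0][1] < 0:
                g = -g
            items = [(v, c // g) for v, c in ints]
            b = b * scale / g
        return Constraint(tuple(items), rel, b)

    # -- convenience -------------------------------------------------
    @staticmethod
    def lower_bound(var: str, value, strict: bool = False) -> "Constraint":
        """``var >= value`` (or ``>`` when strict)."""
        return Constraint.make({var: 1}, ">" if strict else ">=", value)

    @staticmethod
    def upper_bound(var: str, value, strict: bool = False) -> "Constraint":
        """``var <= value`` (or ``<`` when strict)."""
        return Constraint.make({var: 1}, "<" if strict else "<=", value)

    @staticmethod
    def equality(var: str, value) -> "Constraint":
        return Constraint.make({var: 1}, "=", value)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Constraint)
            and self._hash == other._hash
            and self.coeffs == other.coeffs
            and self.rel == other.rel
            and self.const == other.const
        )

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"Constraint({self})"

    @property
    def is_ground(self) -> bool:
        return not self.coeffs

    @property
    def is_strict(self) -> bool:
        return self.rel == "<"

    def ground_truth(self) -> bool:
        assert self.is_ground
        if self.rel == "<=":
            return 0 <= self.const
        if self.rel == "<":
            return 0 < self.const
        return self.const == 0

    def variables(self) -> frozenset[str]:
        return frozenset(self._map)

    def coeff(self, var: str) -> int:
        return self._map.get(var, 0)

    def substitute(self, var: str, expr: Mapping[str, Fraction], const: Fraction) -> "Constraint":
        """Replace ``var`` by the affine expression ``expr + const``."""
        a = self._map.get(var, 0)
        if a == 0:
            return self
        cs: dict[str, Fraction] = {v: Fraction(c) for v, c in self.coeffs if v != var}
        for v, c in expr.items():
            cs[v] = cs.get(v, Fraction(0)) + a * c
        return Constraint.make(cs, self.rel, self.const - a * const)

    def evaluate(self, point: Mapping[str, Fraction]) -> bool:
        lhs = sum((c * _as_rat(point[v]) for v, c in self.coeffs), Fraction(0))
        if self.rel == "<=":
            return lhs <= self.const
        if self.rel == "<":
            return lhs < self.const
        return lhs == self.const

    def negation(self) -> "Constraint":
        """Exact complement; only defined for inequalities."""
        if self.rel == "=":
            raise ValueError("negation of an equality is not a single constraint")
        cs = {v: -c for v, c in self.coeffs}
        rel = "<" if self.rel == "<=" else "<="
        return Constraint.make(cs, rel, -self.const)

    def __str__(self) -> str:
        if not self.coeffs:
            return f"0 {self.rel} {self.const}"
        parts = []
        for i, (v, c) in enumerate(self.coeffs):
            if c == 1:
                term = v
            elif c == -1:
                term = f"-{v}"
            else:
                term = f"{c}*{v}"
            if i and not term.startswith("-"):
                term = "+ " + term
            elif i:
                term = "- " + term[1:]
            parts.append(term)
        return f"{' '.join(parts)} {self.rel} {self.const}"


@dataclass(frozen=True)
class System:
    """A conjunction of constraints over a declared variable universe."""

    constraints: tuple[Constraint, ...]
    universe: frozenset[str]

    @staticmethod
    def of(constraints: Iterable[Constraint], universe: Iterable[str] = ()) -> "System":
        cons = []
        seen = set()
        univ = set(universe)
        for c in constraints:
            univ.update(c._map)
            if c.is_ground:
                if not c.ground_truth():
                    return _false_system(frozenset(univ))
                continue
            if c not in seen:
                seen.add(c)
                cons.append(c)
        return System(tuple(cons), frozenset(univ))

    @property
    def is_false(self) -> bool:
        return any(c.is_ground and not c.ground_truth() for c in self.constraints)

    def conjoin(self, extra: Iterable[Constraint]) -> "System":
        return System.of(list(self.constraints) + list(extra), self.universe)

    def with_universe(self, extra_vars: Iterable[str]) -> "System":
        return System(self.constraints, self.universe | frozenset(extra_vars))

    def evaluate(self, point: Mapping[str, Fraction]) -> bool:
        return all(c.evaluate(point) for c in self.constraints)

    def canonical(self) -> tuple:
        return tuple(sorted(self.constraints, key=lambda c: (c.coeffs, c.rel, c.const)))

    def __str__(self) -> str:
        if self.is_false:
            return "false"
        if not self.constraints:
            return "true"
        return " & ".join(str(c) for c in self.canonical())


def _false_system(universe: frozenset[str]) -> System:
    return System((Constraint((), "<", Fraction(0)),), universe)


# ---------------------------------------------------------------------------
# Fourier-Motzkin elimination
# ---------------------------------------------------------------------------

def _dominance_prune(cons: list[Constraint]) -> list[Constraint] | None:
    """Keep the tightest bound per coefficient vector; None means infeasible."""
    best: dict[tuple, Constraint] = {}
    eqs: dict[tuple, Constraint] = {}
    for c in cons:
        if c.is_ground:
            if not c.ground_truth():
                return None
            continue
        if c.rel == "=":
            prev = eqs.get(c.coeffs)
            if prev is not None and prev.const != c.const:
                return None
            eqs[c.coeffs] = c
            continue
        prev = best.get(c.coeffs)
        if prev is None:
            best[c.coeffs] = c
        else:
            # same lhs: smaller const is tighter; strict beats non-strict at ties
            if (c.const, c.rel != "<") < (prev.const, prev.rel != "<"):
                best[c.coeffs] = c
    out = list(eqs.values())
    for coeffs, c in best.items():
        eq = eqs.get(coeffs)
        if eq is None:
            neg = tuple((v, -k) for v, k in coeffs)
            eq = eqs.get(neg)
            if eq is not None:
                eq = Constraint(coeffs, "=", -eq.const)  # same line, flipped sign
        if eq is not None:
            ok = eq.const <= c.const if c.rel == "<=" else eq.const < c.const
            if not ok:
                return None
            continue
        # opposite-sign pair check: x <= a together with -x <= b means x >= -b
        neg = tuple((v, -k) for v, k in coeffs)
        other = best.get(neg)
        if other is not None:
            lo, hi = -other.const, c.const
            if lo > hi or (lo == hi and (c.rel == "<" or other.rel == "<")):
                return None
        out.append(c)
    return out


def _substitute_equalities(
    cons: list[Constraint], targets: set[str]
) -> tuple[list[Constraint], bool]:
    """Use equalities to eliminate target variables by substitution."""
    changed = True
    while changed:
        changed = False
        for c in cons:
            if c.rel != "=":
                continue
            var = next((v for v, _ in c.coeffs if v in targets), None)
            if var is None:
                continue
            a = c._map[var]
            expr = {v: Fraction(-k, a) for v, k in c.coeffs if v != var}
            k0 = c.const / a
            new = [d.substitute(var, expr, k0) for d in cons if d is not c]
            pruned = _dominance_prune(new)
            if pruned is None:
                return [], False
            cons = pruned
            targets.discard(var)
            changed = True
            break
    return cons, True


def _fm_eliminate_one(cons: list[Constraint], var: str) -> list[Constraint] | None:
    pos, neg, rest = [], [], []
    for c in cons:
        a = c._map.get(var, 0)
        if a > 0:
            pos.append((a, c))
        elif a < 0:
            neg.append((-a, c))
        else:
            rest.append(c)
    for ap, p in pos:
        for aq, q in neg:
            # integer combination: aq*p + ap*q cancels var exactly
            cs = {v: aq * c for v, c in p.coeffs if v != var}
            for v, c in q.coeffs:
                if v != var:
                    cs[v] = cs.get(v, 0) + ap * c
            rel = "<" if (p.rel == "<" or q.rel == "<") else "<="
            rest.append(Constraint.make(cs, rel, aq * p.const + ap * q.const))
    return _dominance_prune(rest)


def eliminate(sys: System, variables: Iterable[str]) -> System:
    """Exact projection of ``sys`` onto ``universe - variables``.

    Equalities are substituted first, then Fourier-Motzkin handles the
    remaining inequalities, cheapest variable (fewest pairwise combinations)
    first.  A point over the remaining variables satisfies the result iff it
    extends to a satisfying point of ``sys``.
    """
    targets = set(variables) & sys.universe
    new_universe = sys.universe - targets
    if sys.is_false:
        return _false_system(new_universe)
    cons = list(sys.constraints)
    cons, ok = _substitute_equalities(cons, targets)
    if not ok:
        return _false_system(new_universe)
    while targets:
        # one pass: pos/neg counts per candidate variable
        counts: dict[str, list[int]] = {v: [0, 0] for v in targets}
        for c in cons:
            for v, a in c.coeffs:
                entry = counts.get(v)
                if entry is not None:
                    entry[0 if a > 0 else 1] += 1
        # deterministic tie-break by name (bit-identical runs)
        var = min(
            targets,
            key=lambda v: (counts[v][0] * counts[v][1] - counts[v][0] - counts[v][1], v),
        )
        targets.discard(var)
        result = _fm_eliminate_one(cons, var)
        if result is None:
            return _false_system(new_universe)
        cons = result
    return System.of(cons, new_universe)


def is_satisfiable(sys: System) -> bool:
    """Exact rational satisfiability via full elimination."""
    if sys.is_false:
        return False
    return not eliminate(sys, sys.universe).is_false


def implies(sys: System, c: Constraint) -> bool:
    """Does every point of ``sys`` satisfy ``c``?  Exact (strict complements)."""
    if sys.is_false:
        return True
    if c.rel == "=":
        return implies(sys, Constraint.make(c._map, "<=", c.const)) and implies(
            sys, Constraint.make(c._map, ">=", c.const)
        )
    return not is_satisfiable(sys.conjoin([c.negation()]))


def subsumes(small: System, big: System) -> bool:
    """True when the solution set of ``small`` is contained in ``big``'s."""
    return all(implies(small, c) for c in big.constraints)


def prune_redundant(sys: System) -> System:
    """Drop constraints entailed by the rest; canonical minimal-ish form."""
    if sys.is_false:
        return _false_system(sys.universe)
    cons = list(sys.canonical())
    i = 0
    while i < len(cons):
        trial = System.of(cons[:i] + cons[i + 1:], sys.universe)
        if implies(trial, cons[i]):
            cons.pop(i)
        else:
            i += 1
    return System.of(cons, sys.universe)


def sample_point(sys: System) -> dict[str, Fraction] | None:
    """An exact rational satisfying point, or None when unsatisfiable.

    Variables are fixed one at a time: project onto the variable, pick a
    value inside its (possibly half-open) interval, substitute, repeat.
    """
    if not is_satisfiable(sys):
        return None
    point: dict[str, Fraction] = {}
    current = sys
    for var in sorted(sys.universe):
        proj = eliminate(current, current.universe - {var})
        lo = hi = None
        lo_strict = hi_strict = False
        for c in proj.constraints:
            a = c.coeff(var)
            if a == 0:
                continue
            bound = c.const / a
            if c.rel == "=":
                lo = hi = bound
                lo_strict = hi_strict = False
                break
            if a > 0:
                if hi is None or bound < hi or (bound == hi and c.is_strict):
                    hi, hi_strict = bound, c.is_strict
            else:
                if lo is None or bound > lo or (bound == lo and c.is_strict):
                    lo, lo_strict = bound, c.is_strict
        if lo is not None and hi is not None:
            value = lo if lo == hi else (lo + hi) / 2
        elif lo is not None:
            value = lo + 1 if lo_strict else lo
        elif hi is not None:
            value = hi - 1 if hi_strict else hi
        else:
            value = Fraction(0)
        point[var] = value
        current = current.conjoin([Constraint.equality(var, value)])
    return point


# ---------------------------------------------------------------------------
# Regions (disjunctions over the parameter universe)
# ---------------------------------------------------------------------------

@dataclass
class Region:
    """Finite disjunction of systems over parameter variables only."""

    disjuncts: list[System]
    universe: frozenset[str] = field(default_factory=frozenset)

    @staticmethod
    def empty(universe: Iterable[str] = ()) -> "Region":
        return Region([], frozenset(universe))

    @property
    def is_empty(self) -> bool:
        return not self.disjuncts

    def simplify(self, *, full: bool = True) -> "Region":
        """Drop unsatisfiable / duplicate / subsumed disjuncts."""
        kept: list[System] = []
        seen = set()
        for d in self.disjuncts:
            if not is_satisfiable(d):
                continue
            if full:
                d = prune_redundant(d)
            key = d.canonical()
            if key in seen:
                continue
            seen.add(key)
            kept.append(d)
        if full and len(kept) > 1:
            out: list[System] = []
            for i, d in enumerate(kept):
                dropped = False
                for j, e in enumerate(kept):
                    if i == j or not subsumes(d, e):
                        continue
                    if subsumes(e, d) and i < j:
                        continue  # equal solution sets: keep the earlier one
                    dropped = True
                    break
                if not dropped:
                    out.append(d)
            kept = out
        kept.sort(key=lambda s: tuple((c.coeffs, c.rel, c.const) for c in s.canonical()))
        return Region(kept, self.universe)

    def contains(self, point: Mapping[str, Fraction]) -> bool:
        return any(d.evaluate(point) for d in self.disjuncts)

    def entails(self, c: Constraint) -> bool:
        """True iff every disjunct implies ``c`` (vacuously true if empty)."""
        return all(implies(d, c) for d in self.disjuncts)

    def conjoin(self, extra: Sequence[Constraint]) -> "Region":
        return Region([d.conjoin(extra) for d in self.disjuncts], self.universe)

    def infimum(self, param: str) -> tuple[Fraction | None, bool]:
        """Exact infimum of ``param`` over the union; (None, False) = unbounded.

        Returns ``(value, attained)``; raises on an empty region.
        """
        if self.is_empty:
            raise ValueError("empty region")
        best: Fraction | None = None
        attained = False
        unbounded = False
        for d in self.disjuncts:
            proj = eliminate(d, d.universe - {param})
            if proj.is_false:
                continue
            lo: Fraction | None = None
            lo_strict = False
            for c in proj.constraints:
                a = c.coeff(param)
                if c.rel == "=":
                    lo, lo_strict = c.const / a, False
                    break
                if a < 0:  # a*param <= b with a < 0  ->  param >= b/a
                    bound = c.const / a
                    if lo is None or bound > lo or (bound == lo and c.is_strict):
                        lo, lo_strict = bound, c.is_strict
            if lo is None:
                unbounded = True
                continue
            if best is None or lo < best:
                best, attained = lo, not lo_strict
            elif lo == best and not lo_strict:
                attained = True
        if unbounded:
            return None, False
        return best, attained

    def __str__(self) -> str:
        if self.is_empty:
            return "empty"
        return " | ".join(f"({d})" for d in self.disjuncts)


# ---------------------------------------------------------------------------
# Tiny concrete-syntax parser for constraints ("h_x - t_dec_min_x >= 0")
# ---------------------------------------------------------------------------

_TOKEN = re.compile(
    r"\s*(?:(?P<num>\d+(?:/\d+)?)|(?P<var>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op><=|>=|=|\+|-|\*))"
)


def parse_constraint(text: str) -> Constraint:
    """Parse a linear constraint in the documented closed syntax.

    Terms: ``var``, ``-var``, ``c*var``, rational constants ``3`` / ``3/2``;
    relations ``<=``, ``=``, ``>=``.
    """
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip():
                raise ValueError(f"cannot parse constraint {text!r} at {text[pos:]!r}")
            break
        tokens.append(m.group(0).strip())
        pos = m.end()

    def parse_side(toks: list[str]) -> tuple[dict[str, Fraction], Fraction]:
        coeffs: dict[str, Fraction] = {}
        const = Fraction(0)
        sign = Fraction(1)
        pending: Fraction | None = None

        def flush_const() -> None:
            nonlocal const, pending, sign
            if pending is not None:
                const += sign * pending
                pending, sign = None, Fraction(1)

        for t in toks:
            if t in ("+", "-"):
                flush_const()
                if t == "-":
                    sign = -sign
            elif t == "*":
                continue
            elif re.fullmatch(r"\d+(/\d+)?", t):
                pending = Fraction(t)
            else:  # variable: consumes any pending coefficient
                c = sign * (pending if pending is not None else Fraction(1))
                coeffs[t] = coeffs.get(t, Fraction(0)) + c
                sign, pending = Fraction(1), None
        flush_const()
        return coeffs, const

    for rel in ("<=", ">=", "="):
        if rel in tokens:
            k = tokens.index(rel)
            lhs_c, lhs_k = parse_side(tokens[:k])
            rhs_c, rhs_k = parse_side(tokens[k + 1:])
            coeffs = dict(lhs_c)
            for v, c in rhs_c.items():
                coeffs[v] = coeffs.get(v, Fraction(0)) - c
            return Constraint.make(coeffs, rel, rhs_k - lhs_k)
    raise ValueError(f"no relation found in {text!r}")
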