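"""Interaction and reaction systems: the qualitative network input.

An IRS is a tuple ``(V, I, R)``: an ordered list of component names, a set of
signed interactions ``(source, sign, target)`` and a set of reactions
``(source, target)`` (the source is consumed into the target).  The
declaration order of ``V`` is significant: it fixes the position of each
component in every sign tuple downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

Interaction = tuple[str, str, str]  # (source, sign, target), sign in {+, -}
Reaction = tuple[str, str]

_SIGNS = ("+", "-")


class IRSError(ValueError):
    """Raised for malformed IRS structures or text."""


@dataclass(frozen=True)
class IRS:
    """Immutable interaction-and-reaction system."""

    components: tuple[str, ...]
    interactions: frozenset[Interaction] = field(default_factory=frozenset)
    reactions: frozenset[Reaction] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seen = set()
        for v in self.components:
            if not v:
                raise IRSError("empty component name")
            if v in seen:
                raise IRSError(f"duplicate component {v!r}")
            seen.add(v)
        for s, a, t in self.interactions:
            if a not in _SIGNS:
                raise IRSError(f"bad interaction sign {a!r}")
            for v in (s, t):
                if v not in seen:
                    raise IRSError(f"interaction endpoint {v!r} not declared")
        for s, t in self.reactions:
            for v in (s, t):
                if v not in seen:
                    raise IRSError(f"reaction endpoint {v!r} not declared")

    @staticmethod
    def of(components, interactions=(), reactions=()) -> "IRS":
        return IRS(tuple(components), frozenset(interactions), frozenset(reactions))

    def index(self, component: str) -> int:
        return self.components.index(component)

    @property
    def n(self) -> int:
        return len(self.components)


def parse_irs(text: str) -> IRS:
    """Parse the line-oriented IRS edge-list dialect.

    Directives (one per line, ``#`` comments)::

        var <name>
        interact <source> (+|-) <target>
        react <source> <target>

    Component order is declaration order.  Re-declaring a component or an
    edge is an error (silent dedup would hide modeling mistakes).
    """
    components: list[str] = []
    interactions: list[Interaction] = []
    reactions: list[Reaction] = []

    def err(lineno: int, msg: str) -> IRSError:
        return IRSError(f"line {lineno}: {msg}")

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        kw = fields[0]
        if kw == "var":
            if len(fields) != 2:
                raise err(lineno, f"expected 'var <name>', got {raw.strip()!r}")
            name = fields[1]
            if name in components:
                raise err(lineno, f"duplicate component {name!r}")
            components.append(name)
        elif kw == "interact":
            if len(fields) != 4 or fields[2] not in _SIGNS:
                raise err(lineno, f"expected 'interact <src> (+|-) <tgt>', got {raw.strip()!r}")
            src, sign, tgt = fields[1], fields[2], fields[3]
            for v in (src, tgt):
                if v not in components:
                    raise err(lineno, f"unknown component {v!r}")
            edge = (src, sign, tgt)
            if edge in interactions:
                raise err(lineno, f"duplicate interaction {src} {sign} {tgt}")
            interactions.append(edge)
        elif kw == "react":
            if len(fields) != 3:
                raise err(lineno, f"expected 'react <src> <tgt>', got {raw.strip()!r}")
            src, tgt = fields[1], fields[2]
            for v in (src, tgt):
                if v not in components:
                    raise err(lineno, f"unknown component {v!r}")
            edge = (src, tgt)
            if edge in reactions:
                raise err(lineno, f"duplicate reaction {src} {tgt}")
            reactions.append(edge)
        else:
            raise err(lineno, f"unknown directive {kw!r}")
    if not components:
        raise IRSError("no components declared")
    return IRS.of(components, interactions, reactions)


def write_irs(irs: IRS) -> str:
    """Emit the same dialect deterministically (declaration order, sorted edges)."""
    lines = [f"var {v}" for v in irs.components]
    order = {v: i for i, v in enumerate(irs.components)}
    for s, a, t in sorted(irs.interactions, key=lambda e: (order[e[0]], order[e[2]], e[1])):
        lines.append(f"interact {s} {a} {t}")
    for s, t in sorted(irs.reactions, key=lambda e: (order[e[0]], order[e[1]])):
        lines.append(f"react {s} {t}")
    return "\n".join(lines) + "\n"


def validate_irs(irs: IRS) -> list[str]:
    """Pure diagnostic pass; returns human-readable warnings.

    Positive auto-regulations never change a derivative sign, so they are
    inert in the hybrid model; isolated components have no incident edge and
    can never switch.  Antagonistic duplicate interactions (both signs
    between the same pair) are legal but worth flagging.
    """
    warnings: list[str] = []
    for s, a, t in sorted(irs.interactions):
        if s == t and a == "+":
            warnings.append(f"inert positive auto-regulation on {s}")
    pairs = sorted({(s, t) for s, a, t in irs.interactions})
    for s, t in pairs:
        if (s, "+", t) in irs.interactions and (s, "-", t) in irs.interactions:
            warnings.append(f"both activation and inhibition from {s} to {t}")
    for v in irs.components:
        if not _can_ever_switch(irs, v):
            warnings.append(f"{v} never switches")
    return warnings


def _can_ever_switch(irs: IRS, v: str) -> bool:
    """Can any transition rule ever flip ``v`` in some location?"""
    for s, a, t in irs.interactions:
        if t == v and not (s == t and a == "+"):
            return True  # I-pos fires when signs differ, I-neg when equal
    for s, t in irs.reactions:
        if t == v:
            return True  # R-target fires when signs differ
        if s == v:
            return True  # R-source fires when v is increasing
    return False


def encode_complex_as_variable(
    irs: IRS,
    members: list[str],
    complex_name: str,
    downstream: list[tuple[str, str]],
) -> IRS:
    """Model a complex of ``members`` as a fresh variable.

    Adds ``complex_name`` to V, a reaction ``(m, complex_name)`` per member,
    and an interaction ``(complex_name, sign, target)`` per downstream pair.
    """
    if not members:
        raise IRSError("empty member list")
    if complex_name in irs.components:
        raise IRSError(f"component {complex_name!r} already declared")
    for m in members:
        if m not in irs.components:
            raise IRSError(f"member {m!r} not declared")
    reactions = set(irs.reactions) | {(m, complex_name) for m in members}
    interactions = set(irs.interactions) | {
        (complex_name, sign, tgt) for sign, tgt in downstream
    }
    return IRS.of(tuple(irs.components) + (complex_name,), interactions, reactions)


def encode_complex_as_duplication(
    irs: IRS,
    members: list[str],
    downstream: list[tuple[str | None, str]],
) -> IRS:
    """Model a complex by duplicating its effects onto every member.

    Each downstream effect is ``(sign, target)``: a regulatory effect when
    sign is ``+``/``-`` (an interaction is added per member) and a reactive
    effect when sign is ``None`` (a reaction is added per member).  No new
    variable is created; duplicated edges collapse by set semantics.
    """
    if not members:
        raise IRSError("empty member list")
    for m in members:
        if m not in irs.components:
            raise IRSError(f"member {m!r} not declared")
    interactions = set(irs.interactions)
    reactions = set(irs.reactions)
    for sign, tgt in downstream:
        if tgt not in irs.components:
            raise IRSError(f"target {tgt!r} not declared")
        for m in members:
            if sign is None:
                reactions.add((m, tgt))
            else:
                interactions.add((m, sign, tgt))
    return IRS.of(irs.components, interactions, reactions)
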