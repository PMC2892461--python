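"""Emit the automaton in the classic PHAVer textual dialect.

One hybrid automaton: a location per sign state with rate-1 clocks, an
invariant per location, and ``when ... sync ... do ... goto`` transitions.
Timing annotations, if given, appear as strengthened guards on the
designated peak transitions.  Output is deterministic (stable ordering), so
exporting twice is byte-identical.  Dialect conformance is best-effort: the
encoding is semantically faithful but not guaranteed to be textually
identical to any particular historical model file.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

from .linconstr import Constraint
from .symbolic import TimingAnnotation, trim_tem
from .tem import TEM, SignState


def _loc_name(state: SignState) -> str:
    return "loc_" + "".join("p" if s == "+" else "m" for s in state)


def _render(c: Constraint) -> str:
    """Human-oriented rendering: negative terms move to the right-hand side."""
    lhs, rhs = [], []
    for v, coef in c.coeffs:
        (lhs if coef > 0 else rhs).append((v, abs(coef)))
    rconst = c.const

    def side(terms, const: Fraction | None) -> str:
        parts = [v if k == 1 else f"{k}*{v}" for v, k in terms]
        if const is not None and (const != 0 or not parts):
            parts.append(str(const))
        return " + ".join(parts) if parts else "0"

    left = side(lhs, -rconst if rconst < 0 else None)
    right = side(rhs, rconst if rconst >= 0 else None)
    rel = {"<=": "<=", "<": "<", "=": "=="}[c.rel]
    return f"{left} {rel} {right}"


def export_phaver(
    tem: TEM,
    annotations: Sequence[TimingAnnotation] = (),
    name: str = "tem",
) -> str:
    """The PHAVer model text for the (optionally trimmed) automaton."""
    automaton = trim_tem(tem, annotations) if annotations else tem
    clocks = list(tem.clocks)
    params = list(tem.param_names())
    lines = [
        f"automaton {name}",
        "contr_var: " + ", ".join(clocks) + ";",
        "parameter: " + ", ".join(params) + ";",
        "synclabs: " + ", ".join(f"peak_{v}" for v in tem.components) + ";",
    ]
    rates = " & ".join(f"{h}' == 1" for h in clocks)
    by_source: dict[SignState, list] = {loc: [] for loc in automaton.locations}
    for e in automaton.edges:
        by_source[e.source].append(e)
    for loc in automaton.locations:
        inv = automaton.invariant(loc)
        inv_text = " & ".join(_render(c) for c in inv) if inv else "true"
        lines.append(f"loc {_loc_name(loc)}: while {inv_text} wait {{{rates}}};")
        for e in by_source[loc]:
            guard = " & ".join(_render(c) for c in e.guard)
            resets = " & ".join(f"{h}' == 0" for h in e.resets)
            lines.append(
                f"  when {guard} sync peak_{e.flipped} do {{{resets}}} "
                f"goto {_loc_name(e.target)};"
            )
    init_clocks = " & ".join(f"{h} == 0" for h in clocks)
    lines.append(f"initially: {_loc_name(automaton.initial)} & {init_clocks};")
    lines.append("end")
    return "\n".join(lines) + "\n"


def parameter_sidecar(tem: TEM) -> str:
    """Sidecar text listing the symbolic parameter names, one per line."""
    return "\n".join(tem.param_names()) + "\n"
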