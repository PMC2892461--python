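"""Packaged example systems and a seeded random-IRS generator.

``two_gene_irs`` is the classic activator/repressor pair whose automaton is a
single four-state cycle.  ``circadian_irs`` is the simplified six-variable
Drosophila circadian network: per/tim mRNAs (M_P, M_T), total PER and TIM
protein pools (P_t, T_t), the cytosolic PER-TIM complex (C) and its nuclear
form (C_N), with the two negative feedback loops of C_N onto the mRNAs.  The
complex is assembled through two separate reactions rather than an explicit
complexation step.
"""

from __future__ import annotations

import importlib.resources
import random

from .irs import IRS, IRSError


def data_path(name: str):
    """Path-like handle to a packaged data file (IRS text, spec configs)."""
    return importlib.resources.files("temkit").joinpath("data", name)


def data_text(name: str) -> str:
    return data_path(name).read_text()


def two_gene_irs() -> IRS:
    """x activates y; y represses x; no reactions."""
    return IRS.of(["x", "y"], interactions=[("x", "+", "y"), ("y", "-", "x")])


def circadian_irs(reverse_transport: bool = False) -> IRS:
    """The simplified circadian network over (M_P, M_T, P_t, T_t, C, C_N).

    The default edge set is the one described by the accompanying running
    text: translation and complex assembly as reactions, plus the two
    negative feedbacks of the nuclear complex on the mRNAs.  It yields a
    64-location automaton with 280 edges.

    With ``reverse_transport=True`` the nuclear export arm of the reversible
    C <-> C_N transport is added as a positive interaction of C_N on C.
    This reconstruction yields exactly 284 edges, matching the published
    transition count for this model; it is off by default because only the
    forward transport is spelled out in the running text.
    """
    interactions = [("C_N", "-", "M_P"), ("C_N", "-", "M_T")]
    if reverse_transport:
        interactions.append(("C_N", "+", "C"))
    return IRS.of(
        ["M_P", "M_T", "P_t", "T_t", "C", "C_N"],
        interactions=interactions,
        reactions=[
            ("M_P", "P_t"),
            ("M_T", "T_t"),
            ("P_t", "C"),
            ("T_t", "C"),
            ("C", "C_N"),
        ],
    )


def random_irs(n_vars: int, n_interactions: int, n_reactions: int, seed: int) -> IRS:
    """A reproducible random IRS without duplicate edges.

    Interaction slots are (source, sign, target) triples, reaction slots are
    ordered (source, target) pairs with source != target; signs uniform.
    """
    if n_vars < 1:
        raise IRSError("need at least one variable")
    names = [f"v{i}" for i in range(n_vars)]
    rng = random.Random(seed)
    interaction_slots = [
        (s, a, t) for s in names for t in names for a in "+-"
    ]
    reaction_slots = [(s, t) for s in names for t in names if s != t]
    if n_interactions > len(interaction_slots) or n_reactions > len(reaction_slots):
        raise IRSError("requested more edges than distinct slots exist")
    interactions = rng.sample(interaction_slots, n_interactions)
    reactions = rng.sample(reaction_slots, n_reactions)
    return IRS.of(names, interactions, reactions)
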