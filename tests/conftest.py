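from __future__ import annotations

from fractions import Fraction

import pytest

import temkit as tk
from temkit.linconstr import parse_constraint


@pytest.fixture(scope="session")
def two_gene_tem() -> tk.TEM:
    return tk.build_tem(tk.two_gene_irs(), ("+", "-"))


@pytest.fixture(scope="session")
def two_gene_cycle() -> tk.CycleSpec:
    return tk.CycleSpec.of(
        [
            {"x": "+", "y": "-"},
            {"x": "+", "y": "+"},
            {"x": "-", "y": "+"},
            {"x": "-", "y": "-"},
            {"x": "+", "y": "-"},
        ],
        closed=True,
    )


@pytest.fixture(scope="session")
def circadian_tem() -> tk.TEM:
    return tk.build_tem(tk.circadian_irs(), ("+",) * 6)


@pytest.fixture(scope="session")
def circadian_cycle() -> tk.CycleSpec:
    return tk.CycleSpec.of(
        [
            {"M_P": "+", "M_T": "+"},
            {"M_P": "-", "M_T": "-"},
            {"M_P": "+", "M_T": "+"},
        ],
        closed=True,
    )


def circadian_annotations() -> tuple[tk.TimingAnnotation, ...]:
    """The 5 h nuclear-complex-peak and 3 h protein-peak guard trimmings."""
    signs = (("M_P", "-"), ("M_T", "-"))
    five = (parse_constraint("h_M_P = 5"), parse_constraint("h_M_T = 5"))
    three = (parse_constraint("h_M_P = 3"), parse_constraint("h_M_T = 3"))
    return (
        tk.TimingAnnotation("C_N", "high", five, signs),
        tk.TimingAnnotation("P_t", "high", three, signs),
        tk.TimingAnnotation("T_t", "high", three, signs),
    )


@pytest.fixture(scope="session")
def circadian_anns() -> tuple[tk.TimingAnnotation, ...]:
    return circadian_annotations()


def generous_params(tem: tk.TEM, lo=0, hi=100) -> dict[str, Fraction]:
    out = {}
    for v in tem.components:
        for phase in "+-":
            out[tk.param_name(v, phase, "min")] = Fraction(lo)
            out[tk.param_name(v, phase, "max")] = Fraction(hi)
    return out
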