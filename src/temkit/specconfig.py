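"""Structured config files: cycle specs, annotations, observers, parameters.

YAML schema (all sections optional except ``cycle``)::

    cycle:
      closed: true
      waypoints:
        - {M_P: "+", M_T: "+"}
        - {M_P: "-", M_T: "-"}
        - {M_P: "+", M_T: "+"}
    annotations:
      - variable: C_N
        peak: high                 # high = + -> -, low = - -> +
        signs: {M_P: "-", M_T: "-"}
        clocks: ["h_M_P = 5", "h_M_T = 5"]
        occurrence: 1              # optional; default: every occurrence
    observers:
      - {name: h_period, reset_at: 0, final: 24}
    init: symbolic                 # symbolic | zero | {x: 7, y: 12}
    max_len: 12                    # optional
    checks: ["t_dec_max_M_P >= 5"] # entailment checks reported by `analyze`

Numeric values must be integers or rational strings like ``"7/2"``; floats
are rejected (the whole pipeline is exact).
"""

from __future__ import annotations

from fractions import Fraction
from typing import Any, Mapping

import yaml

from .linconstr import Constraint, parse_constraint
from .symbolic import CycleSpec, Observer, TimingAnnotation


class ConfigError(ValueError):
    pass


def _rat(value: Any, what: str) -> Fraction:
    if isinstance(value, bool) or isinstance(value, float):
        raise ConfigError(f"{what}: use integers or rational strings, got {value!r}")
    try:
        return Fraction(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{what}: {exc}") from exc


def load_spec_config(text: str) -> dict:
    """Parse a config document into spec / annotations / observers / options."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "cycle" not in doc:
        raise ConfigError("config must be a mapping with a 'cycle' section")
    cyc = doc["cycle"]
    waypoints = cyc.get("waypoints")
    if not waypoints:
        raise ConfigError("cycle.waypoints missing or empty")
    spec = CycleSpec.of(
        [dict(p) for p in waypoints], closed=bool(cyc.get("closed", False))
    )
    annotations = []
    for i, a in enumerate(doc.get("annotations") or ()):
        try:
            conditions = tuple(parse_constraint(c) for c in a.get("clocks", ()))
            annotations.append(
                TimingAnnotation(
                    variable=a["variable"],
                    direction=a.get("peak", "high"),
                    clock_conditions=conditions,
                    sign_preconditions=tuple(sorted((a.get("signs") or {}).items())),
                    occurrence=a.get("occurrence"),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"annotation #{i + 1}: {exc}") from exc
    observers = []
    for i, o in enumerate(doc.get("observers") or ()):
        try:
            observers.append(
                Observer(
                    name=o["name"],
                    final=_rat(o["final"], f"observer #{i + 1} final"),
                    reset_at=int(o.get("reset_at", 0)),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"observer #{i + 1}: missing {exc}") from exc
    checks: list[Constraint] = [parse_constraint(c) for c in doc.get("checks") or ()]
    init = doc.get("init", "symbolic")
    if isinstance(init, Mapping):
        init = {k: _rat(v, f"init[{k}]") for k, v in init.items()}
    elif init not in ("symbolic", "zero"):
        raise ConfigError(f"init must be 'symbolic', 'zero' or a mapping, got {init!r}")
    max_len = doc.get("max_len")
    if max_len is not None:
        max_len = int(max_len)
    period = doc.get("period")
    if period is not None:
        period = _rat(period, "period")
    return {
        "spec": spec,
        "annotations": tuple(annotations),
        "observers": tuple(observers),
        "checks": checks,
        "init": init,
        "max_len": max_len,
        "period": period,
    }


def load_params(text: str) -> dict[str, Fraction]:
    """Parameter assignment file: a flat mapping name -> rational."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ConfigError("parameter file must be a mapping")
    return {str(k): _rat(v, str(k)) for k, v in doc.items()}
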