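# temkit

Exact delay-parameter constraint synthesis for sign-state hybrid models of
biological interaction networks.

A biological network is given as an **interaction and reaction system
(IRS)**: named components, signed regulatory interactions, and
mass-transfer reactions. From it, temkit builds a linear hybrid automaton
whose locations are tuples of derivative signs (one `+`/`-` per component —
"is this concentration currently rising or falling?"), with one clock per
component and four delay parameters per component bounding how long its
rising and falling phases may last. Given a qualitative oscillation
specification — an ordered sequence of partial sign patterns joined by
"eventually" hops, optionally trimmed with experimental timing conditions on
specific concentration peaks — temkit derives, by exact parametric
reachability analysis, the **necessary constraints on the delay parameters**
for that behavior to be realizable. All arithmetic is exact rational;
regions are finite disjunctions of linear constraint systems.

Included:

* IRS data model, line-oriented text format, validation, and the two
  standard complex encodings (`src/temkit/irs.py`)
* automaton construction by the four flip rules, structural parameter
  constraints (`src/temkit/tem.py`)
* exact rational linear-constraint core: Fourier–Motzkin projection,
  satisfiability, entailment, infima, region algebra
  (`src/temkit/linconstr.py`)
* symbolic reachability with time-elapse/discrete-step operators, waypoint
  matching, guard trimming, observer clocks (period analysis), peak-ordering
  enumeration (`src/temkit/symbolic.py`); two interchangeable engines —
  clock-zone polyhedra for small models, a per-path dwell-time encoding for
  large ones — that are cross-checked against each other in the tests
* a concrete-parameter oracle that decides bounded realizability exactly and
  returns a replayable witness schedule (`src/temkit/oracle.py`)
* PHAVer-dialect model export (`src/temkit/export.py`)
* packaged examples: the two-gene activator/repressor pair and the
  simplified six-variable Drosophila circadian network, plus a seeded random
  generator (`src/temkit/examples.py`, `src/temkit/data/`)

## Command line

```sh
# build the automaton and dump it (64 locations for the circadian model)
temkit build fixture:circadian -o circ.json

# derive the necessary parameter region for the packaged elementary
# circadian cycle with its 5 h / 3 h peak-timing conditions
temkit analyze fixture:circadian fixture:circadian-cycle --max-len 7

# concrete check: do these delays admit a realizing run? (prints a witness)
temkit check circ.json params.yaml spec.yaml

# export in the PHAVer textual dialect
temkit export fixture:two-gene -o model.pha --sidecar model.params
```

IRS inputs are files in the documented edge-list dialect (`var x`,
`interact x + y`, `react x y`; see `src/temkit/data/*.irs`) or
`fixture:two-gene` / `fixture:circadian` / `fixture:circadian-full`.
Specs, timing annotations, observer clocks and entailment checks live in a
YAML config (schema documented in `src/temkit/specconfig.py`; example in
`src/temkit/data/circadian_cycle.yaml`).

Every analysis is bounded by a maximum number of discrete steps
(`--max-len`), always echoed in the output: derived regions are exact for
the bounded run set and grow monotonically with the bound.

## Notes

* The circadian fixture reconstructed from the running description alone has
  280 transitions; the published count (284) is reproduced by the fixture's
  `reverse_transport=True` hook, which adds the reverse arm of the nuclear
  transport as a positive interaction of the nuclear complex on the
  cytosolic one. Both variants ship as plain-text IRS files.
* `derive_parameter_region` picks its engine automatically; pass
  `engine="zone"` or `engine="path"` to force one. The path engine prunes
  with a conservative float interval filter but verifies every kept branch
  exactly, so reported regions are exact either way.
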