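# Elementary circadian cycle: per/tim mRNAs in phase, one high and one low
# peak, trimmed by the 5-hour nuclear-complex-peak and 3-hour protein-peak
# timing conditions.
cycle:
  closed: true
  waypoints:
    - {M_P: "+", M_T: "+"}
    - {M_P: "-", M_T: "-"}
    - {M_P: "+", M_T: "+"}
annotations:
  - variable: C_N
    peak: high
    signs: {M_P: "-", M_T: "-"}
    clocks: ["h_M_P = 5", "h_M_T = 5"]
  - variable: P_t
    peak: high
    signs: {M_P: "-", M_T: "-"}
    clocks: ["h_M_P = 3", "h_M_T = 3"]
  - variable: T_t
    peak: high
    signs: {M_P: "-", M_T: "-"}
    clocks: ["h_M_P = 3", "h_M_T = 3"]
init: symbolic
max_len: 7
checks:
  - "t_dec_max_M_P >= 5"
  - "t_dec_max_M_T >= 5"
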