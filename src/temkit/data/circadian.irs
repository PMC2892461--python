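# Simplified Drosophila circadian network (running-text reconstruction).
# M_P, M_T: per/tim mRNAs; P_t, T_t: total PER/TIM protein pools;
# C: cytosolic PER-TIM complex; C_N: nuclear complex.
var M_P
var M_T
var P_t
var T_t
var C
var C_N
interact C_N - M_P
interact C_N - M_T
react M_P P_t
react M_T T_t
react P_t C
react T_t C
react C C_N
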