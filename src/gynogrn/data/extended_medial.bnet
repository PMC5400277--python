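# Medial-domain circuit extended with ARR12, a second SPT-activated
# type-B response regulator modeled as a sink (no outgoing targets).
targets, factors
CK, CK
SPT, SPT
ARR1, SPT
ARR1P, ARR1 & CK
TAA1, SPT & ARR1P
PIN3, SPT & ARR1P
AUX, TAA1
ARR12, SPT
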