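# Lateral-domain circuit: the cytokinin signal is gated by the
# repressors AHP6 (phosphotransfer competitor) and ARR16 (type-A
# feedback repressor), both expressed in the presumptive valves.
# CKSIG is the effective phosphorelay output reaching the type-B ARRs.
targets, factors
CK, CK
SPT, SPT
AHP6, AHP6
ARR16, ARR16
CKSIG, CK & !(AHP6 | ARR16)
ARR1, SPT
ARR1P, ARR1 & CKSIG
TAA1, SPT & ARR1P
PIN3, SPT & ARR1P
AUX, TAA1
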