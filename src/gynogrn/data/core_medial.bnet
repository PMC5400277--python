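# Core medial-domain circuit of the young gynoecium.
# CK (cytokinin) and SPT are self-sustaining inputs; ARR1 is the type-B
# response-regulator transcript, ARR1P its phosphorylated active protein.
# TAA1 (auxin biosynthesis) and PIN3 (auxin efflux) are AND-gates over
# SPT and ARR1P (cooperative regulation); AUX is the produced auxin.
targets, factors
CK, CK
SPT, SPT
ARR1, SPT
ARR1P, ARR1 & CK
TAA1, SPT & ARR1P
PIN3, SPT & ARR1P
AUX, TAA1
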