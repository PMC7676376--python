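FABP4
CFD
GHR
TNFRSF11B
LTF
INS
BCL2
PTEN
PPARG
PDCD1
CXCL12
EP300
TGFBR2
CHI3L1
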