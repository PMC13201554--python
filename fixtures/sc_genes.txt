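INSR
IGF1R
IRS1
IRS2
MK_CD8_1
MK_CD8_2
MK_Tph_1
MK_Tph_2
MK_Treg_1
MK_Treg_2
MK_Vdelta2_1
MK_Vdelta2_2
MK_naive_1
MK_naive_2
MK_proliferating_1
MK_proliferating_2
BIRC5
IFNG
TNF
BG0001
BG0002
BG0003
BG0004
BG0005
BG0006
BG0007
BG0008
BG0009
BG0010
BG0011
BG0012
BG0013
BG0014
BG0015
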