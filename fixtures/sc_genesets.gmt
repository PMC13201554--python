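glycolysis_like	SYN:SC001	BG0003	BG0004	BG0005	BG0006	BG0015
oxphos_like	SYN:SC002	BG0001	BG0002	BG0008	BG0011	BG0013
ppp_like	SYN:SC003	BG0002	BG0006	BG0008	BG0010	BG0015
tca_like	SYN:SC004	BG0002	BG0005	BG0006	BG0008	BG0015
insulin_signaling	SYN:ISM	INSR	IGF1R	IRS1	IRS2
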