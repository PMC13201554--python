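glycolysis_like	SYN:GN001	G0004	G0010	G0015	G0022	G0036	G0039	G0043	G0046	G0053	G0066	G0073	G0077
oxphos_like	SYN:GN002	G0004	G0008	G0015	G0040	G0054	G0057	G0064	G0065	G0075	G0080	G0093	G0094
ppp_like	SYN:GN003	G0013	G0020	G0021	G0025	G0033	G0036	G0039	G0041	G0066	G0077	G0079	G0085
tca_like	SYN:GN004	G0021	G0022	G0023	G0027	G0048	G0054	G0059	G0061	G0062	G0074	G0078	G0099
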