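chr1	2000	5000	G0001	0	+
chr1	27000	30000	G0002	0	-
chr1	52000	55000	G0003	0	+
chr1	77000	80000	G0004	0	-
chr1	102000	105000	G0005	0	+
chr1	127000	130000	G0006	0	-
chr1	152000	155000	G0007	0	+
chr1	177000	180000	G0008	0	-
chr1	202000	205000	G0009	0	+
chr1	227000	230000	G0010	0	-
chr1	252000	255000	G0011	0	+
chr1	277000	280000	G0012	0	-
chr1	302000	305000	G0013	0	+
chr1	327000	330000	G0014	0	-
chr1	352000	355000	G0015	0	+
chr1	377000	380000	G0016	0	-
chr1	402000	405000	G0017	0	+
chr1	427000	430000	G0018	0	-
chr1	452000	455000	G0019	0	+
chr1	477000	480000	G0020	0	-
chr1	502000	505000	G0021	0	+
chr1	527000	530000	G0022	0	-
chr1	552000	555000	G0023	0	+
chr1	577000	580000	G0024	0	-
chr1	602000	605000	G0025	0	+
chr1	627000	630000	G0026	0	-
chr1	652000	655000	G0027	0	+
chr1	677000	680000	G0028	0	-
chr1	702000	705000	G0029	0	+
chr1	727000	730000	G0030	0	-
chr1	752000	755000	G0031	0	+
chr1	777000	780000	G0032	0	-
chr1	802000	805000	G0033	0	+
chr1	827000	830000	G0034	0	-
chr1	852000	855000	G0035	0	+
chr1	877000	880000	G0036	0	-
chr1	902000	905000	G0037	0	+
chr1	927000	930000	G0038	0	-
chr1	952000	955000	G0039	0	+
chr1	977000	980000	G0040	0	-
chr1	1002000	1005000	G0041	0	+
chr1	1027000	1030000	G0042	0	-
chr1	1052000	1055000	G0043	0	+
chr1	1077000	1080000	G0044	0	-
chr1	1102000	1105000	G0045	0	+
chr1	1127000	1130000	G0046	0	-
chr1	1152000	1155000	G0047	0	+
chr1	1177000	1180000	G0048	0	-
chr1	1202000	1205000	G0049	0	+
chr1	1227000	1230000	G0050	0	-
chr2	2000	5000	G0051	0	+
chr2	27000	30000	G0052	0	-
chr2	52000	55000	G0053	0	+
chr2	77000	80000	G0054	0	-
chr2	102000	105000	G0055	0	+
chr2	127000	130000	G0056	0	-
chr2	152000	155000	G0057	0	+
chr2	177000	180000	G0058	0	-
chr2	202000	205000	G0059	0	+
chr2	227000	230000	G0060	0	-
chr2	252000	255000	G0061	0	+
chr2	277000	280000	G0062	0	-
chr2	302000	305000	G0063	0	+
chr2	327000	330000	G0064	0	-
chr2	352000	355000	G0065	0	+
chr2	377000	380000	G0066	0	-
chr2	402000	405000	G0067	0	+
chr2	427000	430000	G0068	0	-
chr2	452000	455000	G0069	0	+
chr2	477000	480000	G0070	0	-
chr2	502000	505000	G0071	0	+
chr2	527000	530000	G0072	0	-
chr2	552000	555000	G0073	0	+
chr2	577000	580000	G0074	0	-
chr2	602000	605000	G0075	0	+
chr2	627000	630000	G0076	0	-
chr2	652000	655000	G0077	0	+
chr2	677000	680000	G0078	0	-
chr2	702000	705000	G0079	0	+
chr2	727000	730000	G0080	0	-
chr2	752000	755000	G0081	0	+
chr2	777000	780000	G0082	0	-
chr2	802000	805000	G0083	0	+
chr2	827000	830000	G0084	0	-
chr2	852000	855000	G0085	0	+
chr2	877000	880000	G0086	0	-
chr2	902000	905000	G0087	0	+
chr2	927000	930000	G0088	0	-
chr2	952000	955000	G0089	0	+
chr2	977000	980000	G0090	0	-
chr2	1002000	1005000	G0091	0	+
chr2	1027000	1030000	G0092	0	-
chr2	1052000	1055000	G0093	0	+
chr2	1077000	1080000	G0094	0	-
chr2	1102000	1105000	G0095	0	+
chr2	1127000	1130000	G0096	0	-
chr2	1152000	1155000	G0097	0	+
chr2	1177000	1180000	G0098	0	-
chr2	1202000	1205000	G0099	0	+
chr2	1227000	1230000	G0100	0	-
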