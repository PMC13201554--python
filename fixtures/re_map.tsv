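chr2	3419873	3421373	E0001	G0100,G0099,G0098
chr2	4167004	4168504	E0002	G0100
chr1	1424907	1426407	E0003	G0050,G0049,G0048
chr1	2498184	2499684	E0004	G0050,G0049,G0048
chr2	595236	596736	E0005	G0075,G0074
chr1	1707504	1709004	E0006	G0050
chr1	4950813	4952313	E0007	G0050,G0049
chr2	2911840	2913340	E0008	G0100,G0099
chr2	4037107	4038607	E0009	G0100,G0099,G0098
chr2	1704618	1706118	E0010	G0100,G0099,G0098
chr1	4224169	4225669	E0011	G0050
chr2	573395	574895	E0012	G0074
chr1	707575	709075	E0013	G0029,G0030
chr1	4041018	4042518	E0014	G0050,G0049,G0048
chr2	2206326	2207826	E0015	G0100,G0099
chr1	1896312	1897812	E0016	G0050
chr1	485816	487316	E0017	G0020
chr2	4407894	4409394	E0018	G0100
chr1	2444338	2445838	E0019	G0050
chr2	3317451	3318951	E0020	G0100
chr1	4823030	4824530	E0021	G0050,G0049,G0048
chr2	4697350	4698850	E0022	G0100,G0099,G0098
chr2	210507	212007	E0023	G0059,G0060,G0058
chr1	1222058	1223558	E0024	G0050,G0049
chr2	3063816	3065316	E0025	G0100,G0099,G0098
chr1	3215266	3216766	E0026	G0050,G0049
chr1	3299792	3301292	E0027	G0050,G0049
chr1	2876064	2877564	E0028	G0050,G0049,G0048
chr2	2196772	2198272	E0029	G0100,G0099
chr2	2734940	2736440	E0030	G0100,G0099,G0098
chr1	2807332	2808832	E0031	G0050,G0049
chr1	261222	262722	E0032	G0011,G0012
chr1	2029923	2031423	E0033	G0050,G0049,G0048
chr1	37943	39443	E0034	G0002,G0003,G0001
chr1	2484547	2486047	E0035	G0050,G0049,G0048
chr2	2664367	2665867	E0036	G0100
chr2	2412767	2414267	E0037	G0100,G0099,G0098
chr2	4801480	4802980	E0038	G0100,G0099
chr1	2813397	2814897	E0039	G0050
chr1	2760803	2762303	E0040	G0050,G0049
chr2	4418958	4420458	E0041	G0100,G0099
chr1	2847616	2849116	E0042	G0050,G0049,G0048
chr1	2054159	2055659	E0043	G0050,G0049,G0048
chr2	190229	191729	E0044	G0059,G0058
chr2	2337949	2339449	E0045	G0100,G0099
chr2	1610333	1611833	E0046	G0100
chr1	4534663	4536163	E0047	G0050
chr2	542360	543860	E0048	G0073,G0072
chr1	395002	396502	E0049	G0017,G0016
chr2	3410373	3411873	E0050	G0100,G0099
chr2	1397554	1399054	E0051	G0100,G0099,G0098
chr1	4515521	4517021	E0052	G0050,G0049
chr2	3944458	3945958	E0053	G0100,G0099,G0098
chr1	2062381	2063881	E0054	G0050,G0049,G0048
chr1	2879514	2881014	E0055	G0050,G0049,G0048
chr2	3218265	3219765	E0056	G0100
chr1	4235756	4237256	E0057	G0050,G0049,G0048
chr1	4329579	4331079	E0058	G0050,G0049
chr2	4759637	4761137	E0059	G0100,G0099
chr1	896761	898261	E0060	G0037
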