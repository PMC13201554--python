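chr1	38150	38793	region	2
chr1	109809	110538	region	2
chr1	133536	134631	region	2
chr1	324331	324868	region	2
chr1	395407	395999	region	2
chr1	788319	789210	region	2
chr1	896955	897938	region	2
chr1	938885	939990	region	2
chr1	1013158	1014333	region	2
chr1	1080797	1081665	region	2
chr1	1222309	1223254	region	2
chr1	1425199	1425947	region	2
chr1	1594191	1595684	region	2
chr1	1703062	1704116	region	2
chr1	2054640	2055472	region	2
chr1	2443540	2444300	region	2
chr1	2444622	2445094	region	2
chr1	3071691	3072751	region	2
chr1	3216136	3216755	region	2
chr1	3265903	3266928	region	2
chr1	3432572	3433509	region	2
chr1	4161375	4162082	region	2
chr1	4329663	4330575	region	2
chr1	4361692	4362719	region	2
chr2	98606	99342	region	2
chr2	190425	190808	region	2
chr2	211053	211412	region	2
chr2	460148	461131	region	2
chr2	574251	574700	region	2
chr2	595340	596198	region	2
chr2	924134	925041	region	2
chr2	1531990	1532947	region	2
chr2	1903886	1905264	region	2
chr2	2412868	2413620	region	2
chr2	2664814	2665623	region	2
chr2	3004840	3006040	region	2
chr2	3318032	3318864	region	2
chr2	3565325	3566351	region	2
chr2	3882091	3882852	region	2
chr2	4037180	4037921	region	2
chr2	4041824	4042662	region	2
chr2	4167314	4168434	region	2
chr2	4672554	4673916	region	2
chr2	4740308	4741300	region	2
chr2	4836178	4836865	region	2
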