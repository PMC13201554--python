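chr1	18517	18897	survivin
chr1	38150	38606	survivin
chr1	69997	70989	survivin
chr1	109809	110394	survivin
chr1	133536	134473	survivin
chr1	291067	291586	survivin
chr1	297760	298298	survivin
chr1	305516	306290	survivin
chr1	324331	324834	survivin
chr1	343395	343917	survivin
chr1	395407	395839	survivin
chr1	473977	474304	survivin
chr1	788319	789162	survivin
chr1	812344	813261	survivin
chr1	815664	816644	survivin
chr1	896955	897677	survivin
chr1	938885	939442	survivin
chr1	1013158	1013431	survivin
chr1	1080797	1081441	survivin
chr1	1119659	1120316	survivin
chr1	1125889	1126789	survivin
chr1	1222309	1222925	survivin
chr1	1277756	1278695	survivin
chr1	1423871	1424786	survivin
chr1	1425199	1425614	survivin
chr1	1447208	1447617	survivin
chr1	1454271	1454664	survivin
chr1	1531616	1531955	survivin
chr1	1594191	1595078	survivin
chr1	1644809	1645622	survivin
chr1	1655982	1656506	survivin
chr1	1657327	1657991	survivin
chr1	1676240	1676895	survivin
chr1	1703062	1703953	survivin
chr1	1709649	1710557	survivin
chr1	1809589	1810066	survivin
chr1	2054640	2055186	survivin
chr1	2129082	2129591	survivin
chr1	2129756	2130621	survivin
chr1	2443540	2443981	survivin
chr1	2444622	2444884	survivin
chr1	2459293	2459805	survivin
chr1	2570217	2570837	survivin
chr1	2673644	2673854	survivin
chr1	2720975	2721784	survivin
chr1	2910041	2910618	survivin
chr1	2938988	2939755	survivin
chr1	3008314	3009217	survivin
chr1	3057450	3058110	survivin
chr1	3071691	3072085	survivin
chr1	3216136	3216435	survivin
chr1	3257848	3258812	survivin
chr1	3265903	3266830	survivin
chr1	3332053	3332593	survivin
chr1	3432572	3433011	survivin
chr1	3461128	3461741	survivin
chr1	3530664	3530985	survivin
chr1	3597957	3598930	survivin
chr1	3600744	3601430	survivin
chr1	3739481	3740319	survivin
chr1	3864076	3864321	survivin
chr1	3956528	3957492	survivin
chr1	4095078	4095367	survivin
chr1	4161375	4161847	survivin
chr1	4182803	4183131	survivin
chr1	4206260	4206667	survivin
chr1	4220331	4220692	survivin
chr1	4237926	4238193	survivin
chr1	4329663	4329995	survivin
chr1	4353198	4353884	survivin
chr1	4354146	4354785	survivin
chr1	4361692	4362539	survivin
chr1	4496041	4496300	survivin
chr1	4510125	4510818	survivin
chr1	4530512	4531383	survivin
chr1	4804971	4805887	survivin
chr2	85847	86675	survivin
chr2	98606	99139	survivin
chr2	148849	149583	survivin
chr2	190425	190804	survivin
chr2	211053	211275	survivin
chr2	431688	432575	survivin
chr2	460148	460494	survivin
chr2	574251	574669	survivin
chr2	595340	595874	survivin
chr2	728132	728925	survivin
chr2	753309	754052	survivin
chr2	809717	810058	survivin
chr2	924134	924866	survivin
chr2	977972	978814	survivin
chr2	1245167	1245876	survivin
chr2	1317868	1318241	survivin
chr2	1462977	1463848	survivin
chr2	1531990	1532928	survivin
chr2	1543576	1544395	survivin
chr2	1615234	1615628	survivin
chr2	1650984	1651237	survivin
chr2	1721461	1722412	survivin
chr2	1761831	1762280	survivin
chr2	1822853	1823197	survivin
chr2	1866003	1866773	survivin
chr2	1903886	1904600	survivin
chr2	1944196	1944902	survivin
chr2	2022520	2023084	survivin
chr2	2055163	2055397	survivin
chr2	2166410	2167244	survivin
chr2	2198557	2199024	survivin
chr2	2243524	2243936	survivin
chr2	2274480	2274793	survivin
chr2	2313967	2314532	survivin
chr2	2331982	2332916	survivin
chr2	2348331	2348943	survivin
chr2	2412868	2413344	survivin
chr2	2445867	2446807	survivin
chr2	2485859	2486456	survivin
chr2	2539625	2540035	survivin
chr2	2577117	2577852	survivin
chr2	2659564	2660204	survivin
chr2	2664814	2665261	survivin
chr2	2753764	2754536	survivin
chr2	2791005	2791295	survivin
chr2	2905523	2906300	survivin
chr2	3004840	3005303	survivin
chr2	3063933	3064920	survivin
chr2	3234106	3235056	survivin
chr2	3239987	3240407	survivin
chr2	3318032	3318585	survivin
chr2	3388821	3389443	survivin
chr2	3428622	3429054	survivin
chr2	3491373	3491582	survivin
chr2	3565325	3566198	survivin
chr2	3678042	3678731	survivin
chr2	3696037	3696885	survivin
chr2	3706317	3707237	survivin
chr2	3799694	3800421	survivin
chr2	3882091	3882780	survivin
chr2	3916680	3917263	survivin
chr2	4037180	4037873	survivin
chr2	4041824	4042028	survivin
chr2	4051163	4051985	survivin
chr2	4060367	4060987	survivin
chr2	4061000	4061494	survivin
chr2	4167314	4168015	survivin
chr2	4433872	4434194	survivin
chr2	4470609	4471285	survivin
chr2	4672554	4673530	survivin
chr2	4717140	4717803	survivin
chr2	4722369	4723243	survivin
chr2	4740308	4740619	survivin
chr2	4836178	4836674	survivin
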