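chr1	38206	38793	H3K27ac
chr1	85551	86203	H3K27ac
chr1	110205	110538	H3K27ac
chr1	134379	134631	H3K27ac
chr1	193507	194219	H3K27ac
chr1	265056	265934	H3K27ac
chr1	296945	297317	H3K27ac
chr1	312051	312441	H3K27ac
chr1	324463	324868	H3K27ac
chr1	343172	343377	H3K27ac
chr1	395783	395999	H3K27ac
chr1	415468	416034	H3K27ac
chr1	430032	430793	H3K27ac
chr1	452348	452707	H3K27ac
chr1	473451	473887	H3K27ac
chr1	499811	500067	H3K27ac
chr1	644962	645265	H3K27ac
chr1	679118	679432	H3K27ac
chr1	731216	732119	H3K27ac
chr1	788651	789210	H3K27ac
chr1	838105	838310	H3K27ac
chr1	897673	897938	H3K27ac
chr1	904986	905767	H3K27ac
chr1	939048	939990	H3K27ac
chr1	1000481	1001381	H3K27ac
chr1	1013420	1014333	H3K27ac
chr1	1081040	1081665	H3K27ac
chr1	1116581	1117097	H3K27ac
chr1	1222715	1223254	H3K27ac
chr1	1281595	1281852	H3K27ac
chr1	1341935	1342173	H3K27ac
chr1	1425432	1425947	H3K27ac
chr1	1440424	1441279	H3K27ac
chr1	1537682	1538096	H3K27ac
chr1	1594911	1595684	H3K27ac
chr1	1633663	1633887	H3K27ac
chr1	1703769	1704116	H3K27ac
chr1	1715518	1716334	H3K27ac
chr1	1740608	1740824	H3K27ac
chr1	1885373	1886235	H3K27ac
chr1	1942135	1942714	H3K27ac
chr1	2055157	2055472	H3K27ac
chr1	2076664	2077217	H3K27ac
chr1	2136938	2137817	H3K27ac
chr1	2344360	2345336	H3K27ac
chr1	2383979	2384260	H3K27ac
chr1	2410396	2410788	H3K27ac
chr1	2443777	2444300	H3K27ac
chr1	2444647	2445094	H3K27ac
chr1	2525485	2526139	H3K27ac
chr1	2561025	2561746	H3K27ac
chr1	2574974	2575840	H3K27ac
chr1	2757500	2758499	H3K27ac
chr1	2790804	2791320	H3K27ac
chr1	2835543	2835978	H3K27ac
chr1	3039817	3040652	H3K27ac
chr1	3071771	3072751	H3K27ac
chr1	3178869	3179295	H3K27ac
chr1	3186359	3187201	H3K27ac
chr1	3216316	3216755	H3K27ac
chr1	3246429	3247176	H3K27ac
chr1	3266374	3266928	H3K27ac
chr1	3387341	3387680	H3K27ac
chr1	3432751	3433509	H3K27ac
chr1	3466849	3467236	H3K27ac
chr1	3470595	3471572	H3K27ac
chr1	3507294	3507904	H3K27ac
chr1	3658832	3659826	H3K27ac
chr1	3733457	3734404	H3K27ac
chr1	3878975	3879861	H3K27ac
chr1	3934045	3935001	H3K27ac
chr1	3945348	3945882	H3K27ac
chr1	3962355	3963304	H3K27ac
chr1	3965967	3966268	H3K27ac
chr1	4088927	4089766	H3K27ac
chr1	4161803	4162082	H3K27ac
chr1	4216505	4217233	H3K27ac
chr1	4271401	4272177	H3K27ac
chr1	4329909	4330575	H3K27ac
chr1	4359468	4360153	H3K27ac
chr1	4362071	4362719	H3K27ac
chr1	4857087	4857501	H3K27ac
chr2	98794	99342	H3K27ac
chr2	190480	190808	H3K27ac
chr2	211154	211412	H3K27ac
chr2	289992	290915	H3K27ac
chr2	294203	295155	H3K27ac
chr2	298213	298464	H3K27ac
chr2	456614	457546	H3K27ac
chr2	460421	461131	H3K27ac
chr2	574394	574700	H3K27ac
chr2	595780	596198	H3K27ac
chr2	631594	632446	H3K27ac
chr2	759534	760192	H3K27ac
chr2	924532	925041	H3K27ac
chr2	1219640	1220632	H3K27ac
chr2	1360172	1361060	H3K27ac
chr2	1385835	1386141	H3K27ac
chr2	1461218	1461570	H3K27ac
chr2	1531007	1531253	H3K27ac
chr2	1532498	1532947	H3K27ac
chr2	1583539	1583863	H3K27ac
chr2	1680569	1681109	H3K27ac
chr2	1686819	1687359	H3K27ac
chr2	1904305	1905264	H3K27ac
chr2	1998453	1999270	H3K27ac
chr2	2053576	2054281	H3K27ac
chr2	2090061	2090397	H3K27ac
chr2	2144344	2145210	H3K27ac
chr2	2168932	2169349	H3K27ac
chr2	2234072	2234624	H3K27ac
chr2	2313151	2313447	H3K27ac
chr2	2339525	2340358	H3K27ac
chr2	2413168	2413620	H3K27ac
chr2	2488116	2488337	H3K27ac
chr2	2556865	2557739	H3K27ac
chr2	2581858	2582181	H3K27ac
chr2	2652402	2653319	H3K27ac
chr2	2665091	2665623	H3K27ac
chr2	2720859	2721367	H3K27ac
chr2	2733903	2734345	H3K27ac
chr2	2899080	2899862	H3K27ac
chr2	2967692	2968172	H3K27ac
chr2	2970187	2970800	H3K27ac
chr2	3005127	3006040	H3K27ac
chr2	3145781	3146162	H3K27ac
chr2	3162785	3163076	H3K27ac
chr2	3318231	3318864	H3K27ac
chr2	3348419	3349073	H3K27ac
chr2	3394102	3394400	H3K27ac
chr2	3487274	3487857	H3K27ac
chr2	3565739	3566351	H3K27ac
chr2	3725946	3726823	H3K27ac
chr2	3845934	3846914	H3K27ac
chr2	3848834	3849758	H3K27ac
chr2	3882311	3882852	H3K27ac
chr2	3928672	3929488	H3K27ac
chr2	4037540	4037921	H3K27ac
chr2	4041890	4042662	H3K27ac
chr2	4087303	4088178	H3K27ac
chr2	4167940	4168434	H3K27ac
chr2	4426463	4426837	H3K27ac
chr2	4461279	4461758	H3K27ac
chr2	4506515	4506735	H3K27ac
chr2	4567405	4568047	H3K27ac
chr2	4652036	4652448	H3K27ac
chr2	4673137	4673916	H3K27ac
chr2	4740594	4741300	H3K27ac
chr2	4836283	4836865	H3K27ac
chr2	4866278	4867051	H3K27ac
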