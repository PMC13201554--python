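planted_enriched	SYN:0001	G00001	G00003	G00007	G00025	G00026	G00034	G00042	G00050	G00057	G00059	G00066	G00082	G00085	G00087	G00091	G00092	G00093	G00102	G00114	G00117	G00118	G00144	G00150	G00165	G00175	G00190	G00193	G00214	G00246	G00255	G00259	G00261	G00270	G00274	G00276	G00285	G00289	G00293	G00296	G00297
random_1	SYN:0002	G00016	G00019	G00035	G00037	G00053	G00067	G00077	G00086	G00092	G00116	G00125	G00132	G00144	G00151	G00152	G00154	G00173	G00174	G00175	G00176	G00183	G00185	G00195	G00208	G00217	G00224	G00227	G00237	G00238	G00252	G00255	G00257	G00258	G00274	G00275	G00285	G00289	G00291	G00292	G00299
random_2	SYN:0003	G00010	G00028	G00029	G00032	G00042	G00045	G00046	G00048	G00062	G00084	G00101	G00105	G00108	G00112	G00115	G00116	G00117	G00131	G00136	G00142	G00149	G00150	G00154	G00158	G00164	G00166	G00172	G00204	G00208	G00211	G00216	G00218	G00219	G00228	G00243	G00260	G00261	G00281	G00287	G00296
random_3	SYN:0004	G00008	G00010	G00012	G00016	G00018	G00030	G00040	G00048	G00072	G00075	G00082	G00090	G00096	G00114	G00121	G00126	G00127	G00131	G00150	G00162	G00189	G00190	G00192	G00196	G00207	G00208	G00210	G00212	G00222	G00226	G00227	G00236	G00240	G00241	G00246	G00257	G00280	G00282	G00288	G00293
random_4	SYN:0005	G00007	G00032	G00041	G00048	G00056	G00065	G00074	G00109	G00131	G00133	G00145	G00148	G00152	G00158	G00160	G00161	G00164	G00168	G00172	G00175	G00188	G00190	G00192	G00209	G00212	G00215	G00219	G00225	G00229	G00232	G00233	G00240	G00244	G00252	G00261	G00265	G00272	G00274	G00283	G00291
random_5	SYN:0006	G00002	G00003	G00007	G00016	G00018	G00025	G00037	G00042	G00069	G00072	G00099	G00102	G00104	G00115	G00119	G00128	G00132	G00134	G00151	G00163	G00165	G00170	G00171	G00177	G00192	G00206	G00231	G00232	G00234	G00238	G00241	G00243	G00245	G00248	G00260	G00270	G00278	G00281	G00290	G00295
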