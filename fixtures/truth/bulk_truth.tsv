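gene_id	responsive	effect_log2
G00001	True	-1
G00002	False	0
G00003	True	-1
G00004	False	0
G00005	False	0
G00006	False	0
G00007	False	0
G00008	False	0
G00009	False	0
G00010	False	0
G00011	False	0
G00012	False	0
G00013	False	0
G00014	False	0
G00015	False	0
G00016	False	0
G00017	False	0
G00018	False	0
G00019	False	0
G00020	False	0
G00021	False	0
G00022	False	0
G00023	False	0
G00024	False	0
G00025	False	0
G00026	False	0
G00027	False	0
G00028	False	0
G00029	False	0
G00030	False	0
G00031	False	0
G00032	False	0
G00033	False	0
G00034	True	1
G00035	False	0
G00036	False	0
G00037	False	0
G00038	False	0
G00039	False	0
G00040	True	-1
G00041	False	0
G00042	False	0
G00043	False	0
G00044	False	0
G00045	False	0
G00046	False	0
G00047	False	0
G00048	False	0
G00049	False	0
G00050	False	0
G00051	False	0
G00052	False	0
G00053	False	0
G00054	True	1
G00055	False	0
G00056	True	-1
G00057	True	-1
G00058	False	0
G00059	True	-1
G00060	False	0
G00061	False	0
G00062	False	0
G00063	False	0
G00064	False	0
G00065	False	0
G00066	False	0
G00067	False	0
G00068	False	0
G00069	False	0
G00070	False	0
G00071	False	0
G00072	False	0
G00073	False	0
G00074	False	0
G00075	False	0
G00076	False	0
G00077	False	0
G00078	False	0
G00079	False	0
G00080	False	0
G00081	False	0
G00082	False	0
G00083	False	0
G00084	False	0
G00085	True	-1
G00086	True	1
G00087	True	1
G00088	False	0
G00089	False	0
G00090	True	-1
G00091	True	-1
G00092	True	-1
G00093	False	0
G00094	False	0
G00095	False	0
G00096	False	0
G00097	False	0
G00098	False	0
G00099	False	0
G00100	False	0
G00101	False	0
G00102	False	0
G00103	False	0
G00104	False	0
G00105	False	0
G00106	False	0
G00107	False	0
G00108	False	0
G00109	False	0
G00110	False	0
G00111	False	0
G00112	False	0
G00113	False	0
G00114	False	0
G00115	False	0
G00116	False	0
G00117	True	-1
G00118	True	-1
G00119	False	0
G00120	False	0
G00121	False	0
G00122	True	1
G00123	False	0
G00124	False	0
G00125	False	0
G00126	False	0
G00127	False	0
G00128	False	0
G00129	False	0
G00130	False	0
G00131	False	0
G00132	False	0
G00133	False	0
G00134	False	0
G00135	False	0
G00136	False	0
G00137	False	0
G00138	False	0
G00139	False	0
G00140	False	0
G00141	False	0
G00142	False	0
G00143	False	0
G00144	False	0
G00145	False	0
G00146	False	0
G00147	False	0
G00148	False	0
G00149	False	0
G00150	False	0
G00151	False	0
G00152	False	0
G00153	False	0
G00154	False	0
G00155	False	0
G00156	False	0
G00157	False	0
G00158	False	0
G00159	False	0
G00160	False	0
G00161	False	0
G00162	False	0
G00163	False	0
G00164	False	0
G00165	True	1
G00166	False	0
G00167	False	0
G00168	False	0
G00169	False	0
G00170	False	0
G00171	False	0
G00172	False	0
G00173	False	0
G00174	False	0
G00175	False	0
G00176	False	0
G00177	False	0
G00178	False	0
G00179	False	0
G00180	False	0
G00181	False	0
G00182	False	0
G00183	False	0
G00184	False	0
G00185	False	0
G00186	False	0
G00187	False	0
G00188	False	0
G00189	False	0
G00190	True	-1
G00191	False	0
G00192	False	0
G00193	False	0
G00194	False	0
G00195	False	0
G00196	False	0
G00197	False	0
G00198	False	0
G00199	False	0
G00200	False	0
G00201	False	0
G00202	False	0
G00203	False	0
G00204	False	0
G00205	False	0
G00206	False	0
G00207	False	0
G00208	False	0
G00209	False	0
G00210	False	0
G00211	True	-1
G00212	False	0
G00213	False	0
G00214	False	0
G00215	False	0
G00216	False	0
G00217	False	0
G00218	False	0
G00219	False	0
G00220	False	0
G00221	False	0
G00222	False	0
G00223	True	-1
G00224	False	0
G00225	False	0
G00226	False	0
G00227	False	0
G00228	False	0
G00229	False	0
G00230	False	0
G00231	False	0
G00232	False	0
G00233	False	0
G00234	False	0
G00235	False	0
G00236	False	0
G00237	False	0
G00238	False	0
G00239	False	0
G00240	False	0
G00241	False	0
G00242	False	0
G00243	False	0
G00244	False	0
G00245	False	0
G00246	False	0
G00247	False	0
G00248	False	0
G00249	False	0
G00250	False	0
G00251	False	0
G00252	False	0
G00253	False	0
G00254	False	0
G00255	True	-1
G00256	False	0
G00257	False	0
G00258	True	-1
G00259	False	0
G00260	False	0
G00261	True	1
G00262	False	0
G00263	False	0
G00264	False	0
G00265	False	0
G00266	False	0
G00267	False	0
G00268	False	0
G00269	False	0
G00270	True	-1
G00271	True	-1
G00272	False	0
G00273	False	0
G00274	True	1
G00275	False	0
G00276	False	0
G00277	False	0
G00278	False	0
G00279	False	0
G00280	False	0
G00281	False	0
G00282	False	0
G00283	False	0
G00284	False	0
G00285	True	-1
G00286	False	0
G00287	False	0
G00288	False	0
G00289	False	0
G00290	False	0
G00291	False	0
G00292	False	0
G00293	True	-1
G00294	False	0
G00295	False	0
G00296	False	0
G00297	True	1
G00298	False	0
G00299	False	0
G00300	False	0
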