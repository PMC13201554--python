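cell	cluster	group	tissue	donor
cell00001	naive	other	ST	P01
cell00002	naive	other	ST	P02
cell00003	CD8	other	ST	P03
cell00004	naive	other	ST	P04
cell00005	Tph	aggressive	ST	P05
cell00006	Treg	other	ST	P01
cell00007	proliferating	aggressive	ST	P02
cell00008	CD8	other	ST	P03
cell00009	CD8	other	ST	P04
cell00010	CD8	other	ST	P05
cell00011	naive	other	ST	P01
cell00012	naive	other	ST	P02
cell00013	Tph	aggressive	ST	P03
cell00014	CD8	other	ST	P04
cell00015	naive	other	ST	P05
cell00016	CD8	other	ST	P01
cell00017	Tph	aggressive	ST	P02
cell00018	naive	other	ST	P03
cell00019	CD8	other	ST	P04
cell00020	Tph	aggressive	ST	P05
cell00021	Treg	other	ST	P01
cell00022	naive	other	ST	P02
cell00023	Treg	other	ST	P03
cell00024	proliferating	aggressive	ST	P04
cell00025	naive	other	ST	P05
cell00026	CD8	other	ST	P01
cell00027	Treg	other	ST	P02
cell00028	CD8	other	ST	P03
cell00029	naive	other	ST	P04
cell00030	CD8	other	ST	P05
cell00031	Treg	other	ST	P01
cell00032	naive	other	ST	P02
cell00033	Treg	other	ST	P03
cell00034	CD8	other	ST	P04
cell00035	Tph	aggressive	ST	P05
cell00036	Treg	other	ST	P01
cell00037	Vdelta2	aggressive	ST	P02
cell00038	naive	other	ST	P03
cell00039	Vdelta2	aggressive	ST	P04
cell00040	CD8	other	ST	P05
cell00041	naive	other	ST	P01
cell00042	Treg	other	ST	P02
cell00043	naive	other	ST	P03
cell00044	Tph	aggressive	ST	P04
cell00045	CD8	other	ST	P05
cell00046	Treg	other	ST	P01
cell00047	naive	other	ST	P02
cell00048	proliferating	aggressive	ST	P03
cell00049	Vdelta2	aggressive	ST	P04
cell00050	naive	other	ST	P05
cell00051	naive	other	ST	P01
cell00052	CD8	other	ST	P02
cell00053	Tph	aggressive	ST	P03
cell00054	CD8	other	ST	P04
cell00055	naive	other	ST	P05
cell00056	CD8	other	ST	P01
cell00057	Treg	other	ST	P02
cell00058	Tph	aggressive	ST	P03
cell00059	naive	other	ST	P04
cell00060	naive	other	ST	P05
cell00061	naive	other	ST	P01
cell00062	Tph	aggressive	ST	P02
cell00063	naive	other	ST	P03
cell00064	Treg	other	ST	P04
cell00065	Vdelta2	aggressive	ST	P05
cell00066	naive	other	ST	P01
cell00067	naive	other	ST	P02
cell00068	Tph	aggressive	ST	P03
cell00069	CD8	other	ST	P04
cell00070	Treg	other	ST	P05
cell00071	CD8	other	ST	P01
cell00072	Tph	aggressive	ST	P02
cell00073	Tph	aggressive	ST	P03
cell00074	Tph	aggressive	ST	P04
cell00075	Treg	other	ST	P05
cell00076	Tph	aggressive	ST	P01
cell00077	naive	other	ST	P02
cell00078	Vdelta2	aggressive	ST	P03
cell00079	Tph	aggressive	ST	P04
cell00080	naive	other	ST	P05
cell00081	CD8	other	ST	P01
cell00082	proliferating	aggressive	ST	P02
cell00083	naive	other	ST	P03
cell00084	Vdelta2	aggressive	ST	P04
cell00085	naive	other	ST	P05
cell00086	CD8	other	ST	P01
cell00087	Treg	other	ST	P02
cell00088	CD8	other	ST	P03
cell00089	naive	other	ST	P04
cell00090	naive	other	ST	P05
cell00091	proliferating	aggressive	ST	P01
cell00092	naive	other	ST	P02
cell00093	proliferating	aggressive	ST	P03
cell00094	Tph	aggressive	ST	P04
cell00095	Tph	aggressive	ST	P05
cell00096	naive	other	ST	P01
cell00097	naive	other	ST	P02
cell00098	naive	other	ST	P03
cell00099	naive	other	ST	P04
cell00100	Tph	aggressive	ST	P05
cell00101	naive	other	ST	P01
cell00102	CD8	other	ST	P02
cell00103	Treg	other	ST	P03
cell00104	Treg	other	ST	P04
cell00105	naive	other	ST	P05
cell00106	CD8	other	ST	P01
cell00107	naive	other	ST	P02
cell00108	CD8	other	ST	P03
cell00109	proliferating	aggressive	ST	P04
cell00110	naive	other	ST	P05
cell00111	naive	other	ST	P01
cell00112	naive	other	ST	P02
cell00113	naive	other	ST	P03
cell00114	naive	other	ST	P04
cell00115	Tph	aggressive	ST	P05
cell00116	CD8	other	ST	P01
cell00117	Tph	aggressive	ST	P02
cell00118	Treg	other	ST	P03
cell00119	Tph	aggressive	ST	P04
cell00120	CD8	other	ST	P05
cell00121	CD8	other	ST	P01
cell00122	CD8	other	ST	P02
cell00123	CD8	other	ST	P03
cell00124	naive	other	ST	P04
cell00125	naive	other	ST	P05
cell00126	naive	other	ST	P01
cell00127	CD8	other	ST	P02
cell00128	CD8	other	ST	P03
cell00129	Treg	other	ST	P04
cell00130	CD8	other	ST	P05
cell00131	Treg	other	ST	P01
cell00132	proliferating	aggressive	ST	P02
cell00133	Treg	other	ST	P03
cell00134	Treg	other	ST	P04
cell00135	naive	other	ST	P05
cell00136	naive	other	ST	P01
cell00137	CD8	other	ST	P02
cell00138	proliferating	aggressive	ST	P03
cell00139	Tph	aggressive	ST	P04
cell00140	proliferating	aggressive	ST	P05
cell00141	CD8	other	ST	P01
cell00142	naive	other	ST	P02
cell00143	Vdelta2	aggressive	ST	P03
cell00144	naive	other	ST	P04
cell00145	Tph	aggressive	ST	P05
cell00146	Vdelta2	aggressive	ST	P01
cell00147	CD8	other	ST	P02
cell00148	CD8	other	ST	P03
cell00149	naive	other	ST	P04
cell00150	proliferating	aggressive	ST	P05
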