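cell	true_high
cell00001	False
cell00002	False
cell00003	False
cell00004	False
cell00005	False
cell00006	False
cell00007	False
cell00008	False
cell00009	False
cell00010	False
cell00011	False
cell00012	True
cell00013	False
cell00014	False
cell00015	False
cell00016	False
cell00017	False
cell00018	False
cell00019	False
cell00020	False
cell00021	False
cell00022	False
cell00023	False
cell00024	False
cell00025	False
cell00026	False
cell00027	False
cell00028	False
cell00029	False
cell00030	False
cell00031	False
cell00032	False
cell00033	False
cell00034	False
cell00035	False
cell00036	True
cell00037	False
cell00038	False
cell00039	False
cell00040	False
cell00041	False
cell00042	False
cell00043	False
cell00044	False
cell00045	False
cell00046	False
cell00047	False
cell00048	False
cell00049	False
cell00050	False
cell00051	False
cell00052	False
cell00053	False
cell00054	False
cell00055	False
cell00056	False
cell00057	False
cell00058	False
cell00059	False
cell00060	False
cell00061	False
cell00062	False
cell00063	False
cell00064	False
cell00065	False
cell00066	True
cell00067	False
cell00068	False
cell00069	False
cell00070	False
cell00071	False
cell00072	False
cell00073	False
cell00074	False
cell00075	False
cell00076	False
cell00077	False
cell00078	False
cell00079	False
cell00080	False
cell00081	False
cell00082	True
cell00083	False
cell00084	True
cell00085	False
cell00086	True
cell00087	False
cell00088	True
cell00089	False
cell00090	False
cell00091	False
cell00092	False
cell00093	False
cell00094	False
cell00095	True
cell00096	False
cell00097	False
cell00098	False
cell00099	False
cell00100	False
cell00101	False
cell00102	False
cell00103	False
cell00104	False
cell00105	False
cell00106	False
cell00107	False
cell00108	False
cell00109	False
cell00110	False
cell00111	False
cell00112	False
cell00113	True
cell00114	True
cell00115	False
cell00116	True
cell00117	False
cell00118	False
cell00119	False
cell00120	False
cell00121	False
cell00122	False
cell00123	False
cell00124	False
cell00125	False
cell00126	False
cell00127	False
cell00128	False
cell00129	False
cell00130	False
cell00131	False
cell00132	False
cell00133	False
cell00134	False
cell00135	False
cell00136	False
cell00137	False
cell00138	False
cell00139	False
cell00140	False
cell00141	False
cell00142	False
cell00143	True
cell00144	False
cell00145	False
cell00146	False
cell00147	False
cell00148	False
cell00149	True
cell00150	False
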