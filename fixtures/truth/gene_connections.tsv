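gene_id	n_elements	element_ids
G0001	1	E0034
G0002	1	E0034
G0003	1	E0034
G0016	1	E0049
G0017	1	E0049
G0037	1	E0060
G0044	1	prom::G0044
G0048	2	E0003,E0043
G0049	5	E0003,E0024,E0026,E0043,E0058
G0050	6	E0003,E0019,E0024,E0026,E0043,E0058
G0058	2	E0023,E0044
G0059	2	E0023,E0044
G0060	1	E0023
G0074	2	E0005,E0012
G0075	1	E0005
G0098	2	E0009,E0037
G0099	2	E0009,E0037
G0100	5	E0002,E0009,E0020,E0036,E0037
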