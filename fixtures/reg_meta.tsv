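unit	insulin
S01	8.11905
S02	10.8723
S03	17.5886
S04	6.47861
S05	7.74777
S06	15.5817
S07	12.433
S08	5.58567
S09	7.43724
S10	8.94584
S11	8.97059
S12	13.1624
S13	8.1864
S14	6.3059
S15	8.93048
S16	18.6651
S17	7.10309
S18	9.74953
S19	12.1249
S20	9.31881
S21	20.7618
S22	5.66632
S23	8.81369
S24	13.1849
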