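site	dft_kcalmol	d3_kcalmol
1α	18.7	14.4
1β	19.1	13.5
2α	15.4	13.4
2β	13.0	9.9
6α	18.1	12.2
6β	10.3	5.3
15α	17.9	14.9
15β	15.5	10.2
18	20.4	13.0
19	22.8	18.3
8	21.1	10.0
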