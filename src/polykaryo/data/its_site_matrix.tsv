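isolate	195	338	538	669
G2	A	T	A	G
G16	A	T	A	G
G19	A	T	A	G
G25A	A	T	A	A
G6	A	T	.	G
G11	A	T	.	G
G13	A	T	.	G
G25B	A	T	.	A
G1	.	C	.	G
G7A	.	C	.	G
G9	.	C	.	G
G24B	.	C	.	G
G7B	.	C	.	A
G24A	.	C	A	G
G3A	.	T	A	G
G30	.	T	.	A
G3B	.	T	.	G
AB509828	N	N	.	G
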