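snp	nucleotide	gene	Cit	Zel	Sur	Kap	Bul	Olt	Alb	Dol	Kos	Kar	Leb	Trn	Cet	Ger
1	A	adcy9	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.11	0.08	1.00	1.00	1.00
2	C	adcy9	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.11	0.08	1.00	1.00	1.00
24	C	hat1	0.09	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	1.00	1.00	1.00
25	C	henmt1	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.02	1.00	1.00	1.00
30	C	hormad1	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.04	0.00	0.00	0.04	1.00	1.00	1.00
32	A	hormad1	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.04	0.00	0.00	0.04	1.00	1.00	1.00
45	T	itpr1	1.00	1.00	1.00	1.00	1.00	1.00	1.00	1.00	1.00	1.00	1.00	0.06	0.00	n.a.
61	G	map3k7	0.04	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	1.00	1.00	1.00
78	G	msh2	1.00	1.00	1.00	1.00	1.00	0.72	1.00	1.00	1.00	1.00	1.00	0.00	0.00	0.00
84	G	parn	1.00	1.00	n.a.	1.00	1.00	1.00	1.00	1.00	1.00	1.00	1.00	0.05	0.00	n.a.
99	C	plk1	0.00	0.00	0.00	0.00	0.06	0.00	0.00	0.00	0.00	0.00	0.00	1.00	1.00	0.95
114	A	rbbp8	0.05	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	1.00	1.00	1.00
124	C	smc1a	0.00	0.00	0.21	0.00	0.00	0.06	0.00	0.00	0.00	0.00	0.00	1.00	1.00	1.00
125	C	smc1a	0.00	0.00	0.21	0.00	0.00	0.06	0.00	0.00	0.00	0.00	0.00	1.00	1.00	1.00
129	T	ywhaz	0.95	1.00	1.00	1.00	1.00	1.00	1.00	1.00	1.00	1.00	1.00	0.00	0.00	0.00
131	C	zfp36	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.05	0.06	1.00	1.00	1.00
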