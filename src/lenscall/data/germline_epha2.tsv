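exon	rsid	hgvs_c	hgvs_p	domain	polyphen2	sift	maf_evs	maf_1000g	maf_panel	n_clear	n_cortical	n_nuclear	n_psc	n_mixed
2	rs147977279	c.121C>G	p.L41V	LBD	0.998 (D)	0.00 (D)	0.0003	0.0000	0.0022	0	1	0	0	0
3	Novel	c.425T>C	p.I142T	LBD	0.959 (D)	0.00 (D)			0.0022	1	0	0	0	0
3	Novel	c.512G>A	p.G171E	LBD	0.883 (P)	0.00 (D)			0.0022	0	1	0	0	0
3	rs147352564	c.523C>T	p.R175C	LBD	0.985 (D)	0.00 (D)	0.0012	0.0000	0.0022	0	1	0	0	0
3	rs6678618	c.570G>A	p.A190A	LBD	synonymous	synonymous	0.3455	0.3586	0.3800	38	27	43	1	32
3	rs6678616	c.573G>A	p.L191L	LBD	synonymous	synonymous	0.3457	0.3586	0.3600	38	26	40	1	28
3	rs34753465	c.648C>T	p.A216A		synonymous	synonymous	0.0053	0.0152	0.0089	0	1	2	0	1
4	Novel	c.852G>A	p.E284E		synonymous	synonymous			0.0022	0	0	0	0	1
5	rs2230597	c.987C>T	p.P329P		synonymous	synonymous	0.4032	0.4444	0.4311	41	30	44	1	35
5	Novel	c.1042T>C	p.W348R		1.000 (D)	0.01 (D)			0.0022	1	0	0	0	0
5	rs374687482	c.1089C>T	p.S363S		synonymous	synonymous	0.0000	0.0000	0.0022	0	0	1	0	0
5	rs34192549	c.1171G>A	p.G391R		0.001 (B)	0.11 (T)	0.0173	0.0101	0.0067	1	1	1	0	1
5	rs55700006	c.1314G>A	p.E438E		synonymous	synonymous	0.0028	0.0000	0.0067	0	0	2	1	0
6	rs55740291	c.1359C>T	p.S453S		synonymous	synonymous	0.0001	0.0000	0.0067	1	0	2	0	0
11	rs55655135	c.1896G>A	p.L632L	TK	synonymous	synonymous	0.0081	0.0101	0.0133	1	2	3	0	0
11	Novel	c.1948G>A	p.A650T	TK	0.433 (B)	0.22 (T)			0.0022	0	0	0	0	1
11	rs10907223	c.1983C>T	p.L661L	TK	synonymous	synonymous	0.0381	0.0404	0.0556	9	6	6	0	4
11	Novel	c.2016C>T	p.H672H	TK	synonymous	synonymous			0.0022	0	0	1	0	0
13	rs116506614	c.2162G>A	p.R721Q	TK	1.000 (D)	0.000 (D)	0.0012	0.0051	0.0044	1	1	0	0	0
13	rs145592908	c.2239G>A	p.V747I	TK	0.999 (D)	0.000 (D)	0.0005	0.0000	0.0044	0	1	1	0	0
14	Novel	c.2326G>A	p.G776S	TK	1.000 (D)	0.00 (D)			0.0022	0	0	1	0	0
14	rs112285834	c.2352C>T	p.T784T	TK	synonymous	synonymous	0.0160	0.0152	0.0489	6	5	2	0	6
15	Novel	c.2491A>G	p.N831D	TK	0.937 (D)	0.00 (D)			0.0044	0	0	0	0	2
15	rs35903225	c.2627G>A	p.R876H		0.999 (D)	0.000 (D)	0.0256	0.0202	0.0089	2	1	0	0	1
15	rs142789236	c.2669G>A	p.R890H		0.999 (D)	0.000 (D)	0.0005		0.0067	2	0	0	0	1
16	Novel	c.2684T>C	p.L895P		1.000 (D)	0.00 (D)			0.0022	0	0	0	0	1
16	Novel	c.2794G>A	p.A932T	SAM	0.000 (B)	1.00 (T)			0.0022	0	0	1	0	0
17	rs3754334	c.2874C>T	p.I958I	SAM	synonymous	synonymous	0.2813	0.3131	0.3200	34	25	37	1	25
17	rs138818894	c.2904G>C	p.Q968H	SAM	0.031 (B)	1.000 (T)	0.0035	0.0000	0.0044	1	0	0	0	1
17	rs114895977	c.2919G>A	p.G973G		synonymous	synonymous	0.0015	0.0000	0.0044	1	0	1	0	0
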