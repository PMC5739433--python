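exon	rsid	cosmic_id	hgvs_c	hgvs_p	polyphen2	sift	maf_evs	maf_1000g	maf_panel	n_clear	n_cortical	n_nuclear	n_psc	n_mixed
4	rs1800370		c.108G>A	p.P36P	synonymous	synonymous	0.0148	0.0051	0.0178	2	1	4		1
4	rs1042522	COSM250061	c.215C>G	p.P72R	0.083 (B)	0.03 (D)	0.2548	0.2424	0.2666	60	38	64	2	46
4	rs751978853		c.354A>T	p.T118T	synonymous	synonymous			0.0022	1				
5	rs375275361	COSM45823	c.558T>C	p.D186D	synonymous	synonymous			0.0022		1			
6	rs1800372	COSM249885	c.639A>G	p.R213R	synonymous	synonymous	0.0193	0.0202	0.0333	7		5		3
8	rs770598448		c.789T>C	p.N263N	synonymous	synonymous			0.0022					1
8	rs730882008	COSM44470	c.845G>T	p.R282L	0.998 (D)	0.00 (D)			0.0022		1			
8	rs200073907	COSM45332	c.885T>C	p.P295P	synonymous	synonymous			0.0044					2
11	rs765530090		c.1113C>A	p.S371S	synonymous	synonymous			0.1800	24	17	26	1	13
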