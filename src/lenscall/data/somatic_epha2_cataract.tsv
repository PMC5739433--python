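contig	pos	ref	alt	func	aachange	cosmic_id	dbsnp_id	exac_af	sift	depth	vaf_percent	dipyrimidine
chr1	16456045	C	T	synonymous SNV	EPHA2:NM_004431:exon16:c.G2709A:p.G903G			1.58E-05		3596	3.81	1
chr1	16456068	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon16:c.C2686T:p.P896S				T	2885	5.03	1
chr1	16456083	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon16:c.G2671A:p.V891M		rs139168333	7.11E-05	T	3220	3.63	0
chr1	16456749	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon15:c.C2641T:p.L881F				D	3694	6.37	1
chr1	16456804	G	A	synonymous SNV	EPHA2:NM_004431:exon15:c.C2586T:p.P862P					5679	4.19	1
chr1	16456871	A	G	nonsynonymous SNV	EPHA2:NM_004431:exon15:c.T2519C:p.M840T				D	1851	3.08	0
chr1	16458249	G	A	synonymous SNV	EPHA2:NM_004431:exon14:c.C2442T:p.G814G					5698	8.80	0
chr1	16458309	G	A	synonymous SNV	EPHA2:NM_004431:exon14:c.C2382T:p.F794F					3319	6.03	1
chr1	16458692	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon13:c.C2192T:p.A731V				D	3257	4.49	1
chr1	16458703	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon13:c.G2181A:p.M727I				D	3645	4.61	1
chr1	16458763	C	T	synonymous SNV	EPHA2:NM_004431:exon13:c.G2121A:p.K707K					635	3.46	1
chr1	16459847	C	T	synonymous SNV	EPHA2:NM_004431:exon11:c.G1881A:p.V627V					2735	4.64	0
chr1	16460407	C	T	synonymous SNV	EPHA2:NM_004431:exon9:c.G1686A:p.R562R					3157	4.25	1
chr1	16462261	G	A	synonymous SNV	EPHA2:NM_004431:exon6:c.C1317T:p.P439P					2620	3.32	1
chr1	16464353	T	C	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.A1307G:p.Q436R				D	3943	3.61	0
chr1	16464600	T	C	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.A1060G:p.S354G				D	2232	6.14	0
chr1	16464608	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.C1052T:p.P351L				D	1669	4.38	1
chr1	16464609	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.C1051T:p.P351S				D	2969	4.65	1
chr1	16464610	G	A	synonymous SNV	EPHA2:NM_004431:exon5:c.C1050T:p.P350P					3004	4.23	1
chr1	16464614	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.C1046T:p.T349M		rs200490325	2.37E-04	D	3066	4.08	0
chr1	16464617	C	T	stopgain	EPHA2:NM_004431:exon5:c.G1043A:p.W348X				T	2426	6.84	1
chr1	16464623	A	G	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.T1037C:p.L346P			7.90E-06	D	2780	3.42	0
chr1	16464624	G	A	synonymous SNV	EPHA2:NM_004431:exon5:c.C1036T:p.L346L					1668	4.62	1
chr1	16464633	T	C	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.A1027G:p.K343E				D	2716	3.57	0
chr1	16464665	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.C995T:p.P332L				D	1708	4.64	1
chr1	16464666	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.C994T:p.P332S				D	1698	4.71	1
chr1	16464790	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon4:c.C959T:p.P320L				T	6624	3.30	1
chr1	16464917	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon4:c.C832T:p.P278S	COSM1185338			T	602	3.49	1
chr1	16474897	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon3:c.G799A:p.E267K				D	2893	6.22	1
chr1	16475162	G	A	synonymous SNV	EPHA2:NM_004431:exon3:c.C534T:p.F178F					6441	3.46	1
chr1	16475177	G	A	synonymous SNV	EPHA2:NM_004431:exon3:c.C519T:p.L173L			2.37E-05		5784	3.46	1
chr1	16475269	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon3:c.G427A:p.D143N				D	3573	8.28	1
chr1	16475541	C	T	stopgain	EPHA2:NM_004431:exon3:c.G155A:p.W52X				T	3510	7.67	1
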