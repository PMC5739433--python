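contig	pos	ref	alt	func	aachange	cosmic_id	dbsnp_id	exac_af	sift	depth	vaf_percent	dipyrimidine
chr1	16451690	G	A	UTR-3	NM_004431:c.*20C>T			1.58E-05		3502	3.94	1
chr1	16451707	G	A	UTR-3	NM_004431:c.*3C>T					4181	3.28	1
chr1	16451720	A	G	nonsynonymous SNV	EPHA2:NM_004431:exon17:c.T2921C:p.I974T				D	4172	3.96	0
chr1	16451809	G	A	synonymous SNV	EPHA2:NM_004431:exon17:c.C2832T:p.I944I					1416	4.31	1
chr1	16451815	G	A	synonymous SNV	EPHA2:NM_004431:exon17:c.C2826T:p.D942D		rs143828420	8.69E-05		1417	4.10	0
chr1	16455972	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon16:c.G2782A:p.A928T				D	3242	12.94	1
chr1	16456009	G	A	synonymous SNV	EPHA2:NM_004431:exon16:c.C2745T:p.S915S					7158	13.87	1
chr1	16456014	C	A	stopgain	EPHA2:NM_004431:exon16:c.G2740T:p.E914X	COSM3934228			D	3242	8.34	0
chr1	16456016	A	G	nonsynonymous SNV	EPHA2:NM_004431:exon16:c.T2738C:p.L913P				D	3048	3.28	0
chr1	16456023	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon16:c.G2731A:p.E911K		rs376030072		D	3991	4.44	1
chr1	16456039	G	A	synonymous SNV	EPHA2:NM_004431:exon16:c.C2715T:p.P905P					3055	5.24	1
chr1	16456067	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon16:c.C2687T:p.P896L				T	2950	5.29	1
chr1	16456744	C	T	synonymous SNV	EPHA2:NM_004431:exon15:c.G2646A:p.K882K					4205	4.04	1
chr1	16456822	C	A	nonsynonymous SNV	EPHA2:NM_004431:exon15:c.G2568T:p.Q856H				D	4309	7.80	0
chr1	16458240	G	A	synonymous SNV	EPHA2:NM_004431:exon14:c.C2451T:p.P817P					6056	3.32	1
chr1	16458257	T	C	nonsynonymous SNV	EPHA2:NM_004431:exon14:c.A2434G:p.T812A				D	5718	3.06	0
chr1	16458352	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon14:c.C2339T:p.P780L				D	1668	8.69	1
chr1	16458353	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon14:c.C2338T:p.P780S				D	1668	5.28	1
chr1	16458579	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon13:c.G2305A:p.E769K		rs367724183	2.37E-05	D	1247	6.52	1
chr1	16458598	G	A	synonymous SNV	EPHA2:NM_004431:exon13:c.C2286T:p.R762R					2564	33.35	0
chr1	16458890	G	A	synonymous SNV	EPHA2:NM_004431:exon12:c.C2098T:p.L700L					1776	3.72	1
chr1	16458893	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon12:c.G2095A:p.A699T	COSM1727288			D	1780	4.22	1
chr1	16458896	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon12:c.G2092A:p.G698R				D	1781	4.27	1
chr1	16458911	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon12:c.G2077A:p.E693K				D	1776	4.23	1
chr1	16458927	G	A	synonymous SNV	EPHA2:NM_004431:exon12:c.C2061T:p.P687P					1775	3.90	1
chr1	16459729	T	C	nonsynonymous SNV	EPHA2:NM_004431:exon11:c.A1999G:p.M667V				D	2940	8.80	0
chr1	16459977	T	C	synonymous SNV	EPHA2:NM_004431:exon10:c.A1863G:p.A621A					3560	3.65	0
chr1	16460030	A	G	nonsynonymous SNV	EPHA2:NM_004431:exon10:c.T1810C:p.F604L				D	2125	4.33	0
chr1	16460049	G	A	synonymous SNV	EPHA2:NM_004431:exon10:c.C1791T:p.P597P					3711	3.18	1
chr1	16460050	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon10:c.C1790T:p.P597L				D	3700	3.22	1
chr1	16460066	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon10:c.C1774T:p.H592Y				D	3736	3.28	1
chr1	16460068	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon10:c.C1772T:p.P591L				D	3486	3.30	1
chr1	16460401	G	A	synonymous SNV	EPHA2:NM_004431:exon9:c.C1692T:p.N564N					1197	7.20	1
chr1	16460407	C	T	synonymous SNV	EPHA2:NM_004431:exon9:c.G1686A:p.R562R					2464	20.06	1
chr1	16460962	C	T	splicing	NM_004431:exon9:c.1682+1G>A					4208	5.28	1
chr1	16461003	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon8:c.C1642T:p.L548F				D	1415	3.67	1
chr1	16461007	G	A	synonymous SNV	EPHA2:NM_004431:exon8:c.C1638T:p.V546V					3799	5.00	1
chr1	16461024	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon8:c.G1621A:p.V541M		rs61731097	2.26E-03	D	3766	3.58	0
chr1	16462157	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon6:c.G1421A:p.R474H				D	4070	3.02	0
chr1	16464354	G	A	stopgain	EPHA2:NM_004431:exon5:c.C1306T:p.Q436X				D	4515	3.43	1
chr1	16464480	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.C1180T:p.R394C			2.37E-05	D	4989	5.46	1
chr1	16464490	G	A	synonymous SNV	EPHA2:NM_004431:exon5:c.C1170T:p.H390H		rs113173342	1.02E-03		4613	4.10	0
chr1	16464498	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.C1162T:p.P388S				D	4640	5.07	1
chr1	16464513	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.G1147A:p.V383M	COSM1205441			D	7947	3.60	0
chr1	16464529	C	T	synonymous SNV	EPHA2:NM_004431:exon5:c.G1131A:p.G377G					2588	3.21	1
chr1	16464550	C	T	stopgain	EPHA2:NM_004431:exon5:c.G1110A:p.W370X				T	7850	3.80	1
chr1	16464553	G	A	synonymous SNV	EPHA2:NM_004431:exon5:c.C1107T:p.C369C					2488	12.42	1
chr1	16464583	G	A	synonymous SNV	EPHA2:NM_004431:exon5:c.C1077T:p.D359D					5120	3.03	0
chr1	16464596	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.G1064A:p.G355E				D	2489	3.50	1
chr1	16464607	A	G	synonymous SNV	EPHA2:NM_004431:exon5:c.T1053C:p.P351P					1090	3.13	0
chr1	16464618	A	G	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.T1042C:p.W348R				D	1808	3.98	0
chr1	16464621	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.C1039T:p.R347C			7.90E-06	D	1442	3.81	0
chr1	16464625	C	T	synonymous SNV	EPHA2:NM_004431:exon5:c.G1035A:p.E345E					1659	18.26	1
chr1	16464641	A	G	nonsynonymous SNV	EPHA2:NM_004431:exon5:c.T1019C:p.M340T				D	1011	4.95	0
chr1	16464655	G	A	synonymous SNV	EPHA2:NM_004431:exon5:c.C1005T:p.L335L					2505	4.47	1
chr1	16464658	G	A	synonymous SNV	EPHA2:NM_004431:exon5:c.C1002T:p.Y334Y					2078	8.81	1
chr1	16464664	T	C	synonymous SNV	EPHA2:NM_004431:exon5:c.A996G:p.P332P					2070	3.54	0
chr1	16464822	A	G	synonymous SNV	EPHA2:NM_004431:exon4:c.T927C:p.C309C					6671	3.36	0
chr1	16475091	G	A	nonsynonymous SNV	EPHA2:NM_004431:exon3:c.C605T:p.P202L				D	3906	4.74	1
chr1	16475108	G	A	synonymous SNV	EPHA2:NM_004431:exon3:c.C588T:p.V196V					3928	3.39	1
chr1	16475144	A	G	synonymous SNV	EPHA2:NM_004431:exon3:c.T552C:p.D184D					2676	10.31	0
chr1	16475374	A	G	nonsynonymous SNV	EPHA2:NM_004431:exon3:c.T322C:p.F108L		rs149867517	7.89E-06	T	5817	4.06	0
chr1	16475408	A	G	synonymous SNV	EPHA2:NM_004431:exon3:c.T288C:p.I96I					4013	12.52	0
chr1	16475446	T	C	nonsynonymous SNV	EPHA2:NM_004431:exon3:c.A250G:p.N84D				T	5681	3.15	0
chr1	16475451	C	T	nonsynonymous SNV	EPHA2:NM_004431:exon3:c.G245A:p.R82H			1.58E-05	D	5662	3.55	0
chr1	16477406	G	A	synonymous SNV	EPHA2:NM_004431:exon2:c.C138T:p.H46H			7.89E-06		4868	4.36	1
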