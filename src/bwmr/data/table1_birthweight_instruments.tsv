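Chr	SNP	Position	Gene	Allele	MAF	BETA	SE	p	N	PVE	F
7	rs138715366	44246271	YKT6-GCK	T/C	0.01	-0.2412	0.0229	7.20E-26	132343	8.38E-04	110.99
17	rs144843919	29037339	SUZ12P1-CRLF3	A/G	0.04	-0.0660	0.0116	1.40E-08	121357	2.67E-04	32.41
3	rs900399	156798732	CCNL1-LEKR1	G/A	0.39	-0.0523	0.0039	2.20E-41	143663	1.25E-03	179.80
22	rs41311445	42070374	SREBF2	C/A	0.10	-0.0445	0.0066	1.60E-11	135729	3.35E-04	45.48
6	rs35261542	20675792	CDKAL1	A/C	0.27	-0.0444	0.0041	4.40E-27	143667	8.16E-04	117.33
2	rs7575873	23962647	ATAD2B	G/A	0.12	-0.0384	0.0057	1.20E-11	139425	3.25E-04	45.33
6	rs10872678	152039964	ESR1	C/T	0.28	-0.0375	0.0041	6.90E-20	143672	5.82E-04	83.66
21	rs2229742	16339172	NRIP1	C/G	0.13	-0.0360	0.0060	2.20E-09	143672	2.51E-04	36.07
4	rs4144829	17903654	LCORL	T/C	0.73	-0.0341	0.0042	5.30E-16	139426	4.73E-04	65.98
8	rs13266210	41533514	ANK1-NKX6-3	G/A	0.21	-0.0308	0.0045	1.30E-11	139429	3.36E-04	46.86
6	rs1187118	34169020	HMGA1	T/A	0.83	-0.0299	0.0051	3.60E-09	137043	2.51E-04	34.41
10	rs2497304	94492716	HHEX-IDE	T/C	0.48	-0.0282	0.0037	2.60E-14	143673	4.04E-04	58.07
9	rs7854962	96900505	PTCH1	G/C	0.22	-0.0279	0.0046	1.90E-09	139424	2.64E-04	36.82
5	rs854037	57091783	5q11.2	G/A	0.19	-0.0268	0.0048	2.20E-08	139429	2.24E-04	31.24
7	rs11765649	23479013	IGF2BP3	C/T	0.25	-0.0267	0.0043	5.80E-10	139428	2.76E-04	38.49
20	rs28530618	31275581	C20orl203	G/A	0.51	-0.0261	0.0038	7.70E-12	138162	3.41E-04	47.13
15	rs7402982	99193269	IGF1R	G/A	0.57	-0.0232	0.0039	2.30E-09	139423	2.54E-04	35.42
8	rs12543725	142247979	SLC45A4	A/G	0.41	-0.0231	0.0038	1.20E-09	139431	2.65E-04	36.96
7	rs798498	2795882	GNA12	G/T	0.31	-0.0229	0.0040	1.30E-08	139427	2.35E-04	32.77
3	rs2168443	46947087	PTH1R	A/T	0.62	-0.0228	0.0039	3.50E-09	139426	2.45E-04	34.17
15	rs12906125	91427612	FES	A/G	0.32	-0.0228	0.0040	1.70E-08	141281	2.30E-04	32.50
22	rs134594	29468456	KREMEN1	T/C	0.65	-0.0227	0.0040	1.00E-08	137340	2.34E-04	32.14
13	rs7998537	40662742	LINC00332	A/G	0.32	-0.0222	0.0040	3.90E-08	139429	2.21E-04	30.82
3	rs10935733	148622968	CPA3	C/T	0.59	-0.0221	0.0039	9.20E-09	139426	2.30E-04	32.07
12	rs2306547	26877885	ITPR2	T/C	0.46	-0.0211	0.0037	1.80E-08	139432	2.33E-04	32.49
9	rs1411424	113892963	LPAR1	A/G	0.52	0.0212	0.0038	2.20E-08	139428	2.23E-04	31.10
6	rs9368777	33788637	HMGA1	C/G	0.58	0.0215	0.0038	2.20E-08	135709	2.36E-04	32.03
17	rs72833480	45964861	SP6-SP2	A/G	0.29	0.0226	0.0041	4.60E-08	139426	2.18E-04	30.40
20	rs6040076	10658882	JAG1	C/G	0.49	0.0231	0.0039	2.00E-09	139424	2.52E-04	35.14
16	rs28415607	19993015	GPR139	C/T	0.25	0.0233	0.0043	5.00E-08	143660	2.04E-04	29.31
20	rs6016377	39172728	MAFB	T/C	0.43	0.0239	0.0039	9.50E-10	139425	2.69E-04	37.51
5	rs2946179	157886627	EBF1	C/T	0.73	0.0240	0.0042	1.30E-08	143666	2.27E-04	32.62
4	rs2131354	145599908	HHIP	A/G	0.53	0.0259	0.0037	4.10E-12	139431	3.51E-04	48.96
1	rs3753639	154986091	ZBTB7B	C/T	0.24	0.0306	0.0045	7.30E-12	138162	3.35E-04	46.30
17	rs113086489	7171356	CLDN7	T/C	0.56	0.0307	0.0038	9.10E-16	139426	4.68E-04	65.28
1	rs72480273	161644871	FCGR2B	C/A	0.17	0.0313	0.0051	8.00E-10	138380	2.72E-04	37.65
1	rs2473248	22536643	WNT4-ZBTB40	C/T	0.87	0.0325	0.0057	1.00E-08	139428	2.33E-04	32.49
13	rs1819436	78580283	RNF219-AS1	C/T	0.87	0.0329	0.0057	6.30E-09	138979	2.40E-04	33.36
9	rs10818797	126020405	STRBP	C/T	0.14	0.0345	0.0054	1.20E-10	139427	2.93E-04	40.86
10	rs740746	115792787	ADRB1	A/G	0.73	0.0364	0.0042	3.80E-18	143672	5.23E-04	75.18
10	rs79237883	104940946	NT5C2	C/T	0.08	0.0371	0.0067	3.50E-08	143666	2.13E-04	30.61
12	rs7964361	102994878	IGF1	A/G	0.09	0.0391	0.0067	4.70E-09	139428	2.44E-04	34.03
3	rs11719201	123068744	ADCY5	T/C	0.23	0.0463	0.0044	2.40E-26	143670	7.70E-04	110.71
2	rs17034876	46484310	EPAS1	T/C	0.70	0.0471	0.0042	2.60E-29	134460	9.34E-04	125.70
11	rs72851023	2130620	INS-IGF2	T/C	0.07	0.0476	0.0075	2.90E-10	135776	2.97E-04	40.34
7	rs111778406	72957570	MLXIPL	G/A	0.07	0.0492	0.0075	5.80E-11	140932	3.05E-04	43.00
9	rs3780573	98239503	PTCH1	A/G	0.10	0.0555	0.0064	7.00E-18	134750	5.58E-04	75.23
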