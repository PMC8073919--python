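chrom	pos	rsid	effect_allele	beta	p_value	cadd_phred	gene
1	15539953	rs1316277	T	-3.51	0.00021	14.2	TMEM51
1	165140258	rs7540787	T	-2.7	0.00064	11.8	LMX1A
12	40441521	rs10878035	C	4.85	0.00009	16.5	SLC2A13
13	77062997	rs581121	T	3.17	0.00048	13.1	KCTD12
13	89392881	rs4270027	G	-3.3	0.00039	12.4	SLITRK5
14	86791228	rs1505187	A	3.63	0.00033	10.0	
15	95588003	rs8031253	T	2.98	0.00057	11.2	MCTP2
18	25760028	rs11564299	G	3.44	0.00041	15.7	CDH2
2	201253769	rs3739118	A	2.81	0.00062	17.3	SPATS2L
3	60531242	rs6807877	A	5.36	0.00005	19.6	FHIT
4	126967979	rs6534528	G	-3.77	0.00018	12.9	FAT4
4	12935474	rs6811193	G	-4.23	0.00012	14.8	RAB28
5	32581603	rs6876035	T	2.58	0.00077	10.6	SUB1
6	36772543	rs9296197	G	3.95	0.00016	18.2	CPNE5
8	103190097	rs1265121	T	2.8	0.00059	13.6	NCALD
9	37666010	rs2057643	C	3.5	0.00028	16.1	FRMPD1
7	45120033	rs9990001	A	2.11	0.001	15.0	DECOY1
11	8822710	rs9990002	C	-1.95	0.0042	22.4	DECOY2
16	60233941	rs9990003	G	3.02	0.052	13.3	DECOY3
2	11048267	rs9990004	T	-2.44	0.00031	9.99	DECOY4
5	140882201	rs9990005	A	1.87	0.00072	8.2	DECOY5
10	29941175	rs9990006	G	-3.14	0.00055	5.6	DECOY6
19	4471208	rs9990007	C	2.63	0.00044		DECOY7
22	30180559	rs9990008	T	-1.52	0.0099	3.1	DECOY8
6	150342611	rs9990009	A	2.95	0.0012	11.4	DECOY9
17	73294805	rs9990010	G	-2.08	0.00088	0.4	DECOY10
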