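Chr	bp	rsID	EffectAllele	Beta	P	CADD	Gene
1	15539953	rs1316277	T	-3.51			TMEM51
1	165140258	rs7540787	T	-2.7			LMX1A
12	40441521	rs10878035	C	4.85			SLC2A13
13	77062997	rs581121	T	3.17			KCTD12
13	89392881	rs4270027	G	-3.3			SLITRK5
14	86791228	rs1505187	A	3.63			
15	95588003	rs8031253	T	2.98			MCTP2
18	25760028	rs11564299	G	3.44			CDH2
2	201253769	rs3739118	A	2.81			SPATS2L
3	60531242	rs6807877	A	5.36			FHIT
4	126967979	rs6534528	G	-3.77			FAT4
4	12935474	rs6811193	G	-4.23			RAB28
5	32581603	rs6876035	T	2.58			SUB1
6	36772543	rs9296197	G	3.95			CPNE5
8	103190097	rs1265121	T	2.8			NCALD
9	37666010	rs2057643	C	3.5			FRMPD1
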