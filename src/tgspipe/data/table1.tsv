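rsid	localization	alleles	nearest_gene	OR	p_value	trait
rs12946520	downstream	A/G	SPEM3	0.49	1.13e-4	testosterone measurement
rs1112195	intergenic	T/C	NR1D2,LINC00691	0.59	1.37e-3	testosterone measurement
rs11235688	UTR3	C/T	P2RY2	0.61	1.55e-3	testosterone measurement
rs12443881	intronic	T/G	ATXN2L	0.52	2.06e-3	testosterone measurement
rs12261919	intronic	G/C	DNMBP	0.64	2.41e-3	testosterone measurement
rs7610095	intronic	G/A	MBNL1	1.47	4.23e-3	testosterone measurement
rs11705936	intronic	C/T	CCDC12	0.69	4.53e-3	testosterone measurement
rs28576256	intronic	A/G	BCL11B	1.70	5.10e-3	testosterone measurement
rs5752773	intronic	G/A	CHEK2	0.62	6.43e-3	testosterone measurement
rs1822246	intergenic	G/T	LINC00924,LOC105369212	1.51	6.44e-3	testosterone measurement
rs2583949	ncRNA_intronc	T/C	RPSAP52	0.53	6.62e-3	testosterone measurement
rs4606447	intronic	G/A	ATG13	1.47	2.99e-3	reaction time measurement
rs4673905	intergenic	G/A	MAIP1,SPATS2L	1.43	5.93e-3	reaction time measurement
rs1465370	intergenic	T/G	CPA5,CPA1	0.67	4.49e-3	physical activity measurement
rs1998710	ncRNA_intronc	C/T	LINC01720	0.68	4.68e-3	physical activity measurement
rs2241423	intronic	C/T	MAP2K5	1.43	5.62e-3	physical activity measurement
rs10956487	intergenic	A/G	CCDC26,GSDMC	0.59	9.90e-4	lean body mass
rs16909970	intergenic	G/C	PTCH1,LINC00476	1.63	1.43e-3	lean body mass
rs151181	intronic	A/G	CLN3	0.51	2.07e-3	lean body mass
rs3219175	upstream	G/A	RETN	1.70	2.24e-3	lean body mass
rs17010957	intronic	G/A	ARHGAP24	0.59	2.48e-3	lean body mass
rs7998317	intronic	C/T	DOCK9	1.44	4.58e-3	lean body mass
rs11902369	intergenic	GTT/G	GAD1,GORASP2	0.68	4.81e-3	lean body mass
rs9322334	intronic	T/C	ESR1	0.66	7.82e-3	lean body mass
rs4291686	intergenic	G/A	DDX6,CXCR5	0.69	8.16e-3	lean body mass
rs868554	intronic	G/C	GPR139	0.69	9.86e-3	lean body mass
rs6722871	intergenic	A/G	SERPINE2,FAM124B	0.64	9.12e-3	interleukin-6 measurement
rs34916901	upstream	G/C	H4C8	1.77	1.07e-3	hand grip strength
rs4677611	intronic	A/G	FOXP1	1.46	7.30e-3	hand grip strength
rs2744475	intergenic	C/T	TFAP2D,TFAP2B	1.43	7.39e-3	hand grip strength
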