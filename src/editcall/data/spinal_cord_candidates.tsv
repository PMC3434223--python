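position	gene	ref	st	cov_rna	bcr_a	bcr_c	bcr_g	bcr_t	bcrf_a	bcrf_c	bcrf_g	bcrf_t	cov_exome	bce_a	bce_c	bce_g	bce_t	pct_editing	pvalue	llr	known_edited
chr9:35688080	TLN1	T	TC	196	0	79	0	117	0	150	0	122	21	0	0	0	21	40.31	4.05e-27	321.98	0
chr9:139026134	ABCA2	T	TC	377	0	76	0	301	0	152	0	508	0	0	0	0	0	20.16	8.51e-24	ND	0
chr16:357758	MRPL28	T	TC	116	0	60	0	56	0	63	0	58	6	0	0	0	6	51.72	1.02e-21	176.42	0
chr1:1299268	AURKAIP1	T	TC	93	0	43	0	50	0	58	0	55	1	0	0	0	1	46.24	5.54e-15	120.94	0
chr17:19624930	ULK2	T	TC	116	0	42	0	74	0	86	0	80	6	0	0	0	6	36.21	6.36e-14	111.03	0
chr4:78198704	CCNI	T	TC	174	0	35	0	139	0	54	0	151	28	0	0	0	28	20.11	8.89e-11	125.07	1
chr4:191101378	FRG1	A	AG	71	54	0	17	0	56	0	20	0	0	0	0	0	0	23.94	2.74e-05	ND	0
chrX:153233144	FLNA	T	TC	76	0	17	0	59	0	51	0	69	5	0	0	0	5	22.37	2.95e-05	78.04	1
chr11:61481492	BEST1	A	AG	106	89	0	17	0	95	0	18	0	4	4	0	0	0	16.04	3.89e-05	39.64	0
chr12:6043772	VWF	T	TC	133	0	15	0	118	0	15	0	133	2	0	0	0	2	11.28	1.80e-04	29.77	0
chr4:191115593	FRG1	A	AG	59	45	0	14	0	45	0	15	0	159	159	0	0	0	23.73	2.28e-04	35.87	0
chr17:37235419	NT5C3L	T	TC	45	0	13	0	32	0	20	1	67	2	0	0	0	2	28.89	3.82e-04	37.26	0
chr3:58116831	FLNB	A	AG	105	92	0	13	0	101	0	15	0	11	11	0	0	0	12.38	6.52e-04	28.84	0
chr1:224041237	SRP9	A	AG	30	19	0	11	0	21	0	22	0	0	0	0	0	0	36.67	1.23e-03	ND	1
chr15:20421437	TUBGCP5	A	AG	53	42	0	11	0	46	0	16	0	8	8	0	0	0	20.75	1.96e-03	25.85	0
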