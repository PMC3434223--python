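position	gene	ref	st	cc	aac	codp	cov_rna	bcr_a	bcr_c	bcr_g	bcr_t	bcrf_a	bcrf_c	bcrf_g	bcrf_t	pct_editing	pvalue	fdr	known_edited	validated_exome
chr4:57670991	IGFBP7	T	TC	AAG>AGG	K>R	2	263	0	167	0	96	0	189	0	173	63.5	2.62e-66	1.41e-63	1	0
chr5:156669386	CYFIP2	A	AG	AAG>GAG	K>E	1	153	63	0	90	0	66	0	113	0	58.82	2.75e-34	7.40e-32	1	0
chr1:116739332	ATP1A1	A	AG	ATC>GTC	I>V	1	478	414	0	64	0	486	0	94	1	13.39	2.00e-19	3.58e-17	0	0
chr4:158500744	GRIA2	A	AG	AGA>GGA	R>G	1	75	33	0	42	0	36	0	50	0	56	2.00e-15	2.69e-13	1	0
chr19:59638596	TTYH1	A	AG	CTA>CTG	L>L	3	228	180	0	48	0	245	2	66	0	21.05	6.21e-15	6.69e-13	0	0
chr1:224041237	SRP9	A	AG	ATA>ATG	I>M	3	57	26	0	31	0	27	0	41	0	54.39	3.47e-11	3.12e-09	1	0
chr4:158477325	GRIA2	A	AG	CAG>CGG	Q>R	2	22	1	0	21	0	1	0	28	0	95.45	2.31e-10	1.77e-08	1	0
chrX:122426643	GRIA3	A	AG	AGA>GGA	R>G	1	22	3	0	19	0	3	0	24	0	86.36	1.94e-08	1.31e-06	1	0
chr15:73433139	NEIL1	A	AG	AAA>AGA	K>R	2	15	0	0	15	0	0	0	33	0	100	1.03e-07	6.18e-06	1	0
chr6:44228327	TMEM63B	A	AG	CAG>CGG	Q>R	2	92	70	0	22	0	95	0	24	0	23.91	7.73e-07	4.17e-05	0	0
chrX:153233144	FLNA	T	TC	CAG>CGG	Q>R	2	67	0	20	0	47	0	22	0	50	29.85	2.30e-06	1.12e-04	1	0
chr11:105309904	GRIA4	A	AG	AGA>GGA	R>G	1	19	4	0	15	0	6	0	17	0	78.95	3.35e-06	1.51e-04	1	0
chr2:267003	ACP1	A	AG	CAA>CGA	Q>R	2	44	26	0	18	0	26	0	18	0	40.91	5.24e-06	2.17e-04	0	1
chr6:102479282	GRIK2	A	AG	CAG>CGG	Q>R	2	13	2	0	11	0	2	0	11	0	84.62	1.06e-04	4.09e-03	1	0
chr21:33845189	SON	A	AG	CTA>CTG	L>L	3	35	21	0	14	0	26	0	17	0	40	1.17e-04	4.21e-03	0	0
chr19:8484035	ZNF414	T	TC	CAG>CGG	Q>R	2	54	0	13	0	41	0	14	0	55	24.07	4.51e-04	1.52e-02	0	0
chr14:25987370	NOVA1	T	TC	AGC>GGC	S>G	1	30	0	12	0	18	0	14	0	23	40	5.25e-04	1.67e-02	0	0
chr16:357758	MRPL28	T	TC	TAT>TGT	Y>C	2	104	0	13	0	91	0	14	0	104	12.5	6.50e-04	1.95e-02	0	1
chr20:35580977	BLCAP	T	TC	CAG>CGG	Q>R	2	110	0	12	0	98	0	12	1	124	10.91	1.31e-03	3.71e-02	1	0
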