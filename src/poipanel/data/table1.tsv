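n_patients	gene	variant_type	aa_change	gnomad_nfe_af	eur_af_1kg	sift	polyphen	cadd_phred	mutation_taster	grantham	acmg_criteria	classification
3	DNAH5	missense	S3774P	0.00013	NA	0	0.529	27.8	B	74	PP2, PP3, PM2, PM1	LP
2	DNAH5	missense	I3568T	0.00881	NA	0.23	0.001	21.9	B	89	PP2, PM2, PM1	VUS
1	DNAH5	missense	Q2949E	0.00315	0.002	0.08	0.002	21.4	D	29	PP2, PM2, PM1	VUS
1	DNAH5	missense	S2605L	NA	NA	0.08	0.028	23.7	D	145	PP2, PP3, PM6, PM1, PM2	LP
1	DNAH5	missense	N1420D	0.00041	0.0061	0.28	0.005	22.8	B	23	PP2, PM2, PM1, PM2	VUS
1	DNAH5	missense	L1339R	0.00019	0.002	0.6	0	18.98	B	102	PP2, PM2	VUS
1	DNAH5	missense	N934S	NA	NA	0.89	0	0.11	B	46	PP2, PM2	VUS
2	DNAH5	missense	T806I	0.01763	NA	0.28	0	15.24	B	58	PP2, PM2	VUS
1	DNAH5	missense	A769V	0.07048	NA	1	0	0.42	B	64	PP2, PM2	VUS
1	DNAH5	missense	Y4308C	0.09694	NA	0.05	0.03	18.84	B	194	PP2, BS1, BP4, BP6	LB
3	LAMC1	missense	R1011H	0.00078	0.001	0.07	1	27.1	D	29	PP2, PM5, PM2, PM1	LP
1	LAMC1	missense	Y1035S	NA	NA	0	1	28.4	D	144	PM2, PM5, PP2, PP3	LP
1	LAMC1	missense	A1239V	NA	NA	0.37	0.858	17.33	B	64	PM2, PP2	VUS
1	LAMC1	missense	A1335S	NA	NA	0.01	0.999	23.3	B	99	PP2, PP3, PM2, PM6	LP
1	HSD17B4	missense	I53M	NA	NA	NA	NA	5.95	B	10	PM6, PM1, PM2	LP
1	HSD17B4	missense	C214S	0.00004	NA	0.04	0.217	28.4	NA	112	PP3, PM2	VUS
1	HSD17B4	missense	R658H	NA	NA	0.03	0.984	23.6	B	103	PP3, PM1, PM2	VUS
1	HSD17B4	missense	A741S	NA	NA	0	0.752	26.5	B	99	PP3, PM6, PM1, PM2	LP
1	HK3	missense	P676S	0.00021	0.001	0.02	0.588	18.49	B	74	PP2, PP3, PM2	VUS
2	HK3	missense	Q600H	0.01082	0.008	0.15	0	19.02	B	24	PP2, PM2, PM1	VUS
1	HK3	missense	I347T	0.00011	NA	0	0.904	23.8	B	89	PP2, PP3, PM2, PM1	LP
1	HK3	missense	C237R	NA	NA	0	1	24.1	D	180	PM2, PM5, PP2, PP3	LP
3	PCDH11X	missense	T790S	0.03674	NA	0.08	0.035	5.332	B	32	PM2, PM1, PP2	VUS
1	PCDH11X	missense	R1010I	0.04897	NA	0	0.999	23.2	B	64	PM1, PM2, PP3, PP2	LP
2	AR	inframe_deletion	Q74_Q80del	NA	NA	NA	NA	13.48	D	NA	PM4, PM1, PM2	LP
1	AR	inframe_deletion	Q66_Q80del	NA	NA	NA	NA	13.48	D	NA	PM4, PM1, PM2	LP
1	NOTCH2	missense	I1693T	NA	NA	0.01	0.039	22.8	B	32	PM2, PP2	VUS
1	NOTCH2	missense	R318L	0.01764	NA	0.12	0.001	22.4	B	102	PM2, PM1, PP2	VUS
1	NOTCH2	missense	A147S	0.00885	NA	0.34	0.932	22.7	B	99	PM1, PM2, PP2, PP3	LP
1	ADAMTS19	missense	R64C	NA	NA	0	0.959	18.07	B	180	PM1, PM2, PP2, PP3	LP
1	ADAMTS19	missense	L117V	NA	NA	0.02	0	12.17	B	32	PM1, PM2	VUS
1	ADAMTS19	missense	G202S	0.00018	NA	0.35	0.005	13.87	B	56	PM1, PM2, BS1, BP4, BP6	LB
1	FANCM	missense	A48D	NA	NA	0.01	0.068	14.8	B	126	PM6, PM1, PM2	LP
1	FANCM	missense	L57F	0.00282	0.002	0.01	0.068	14.75	B	126	PM2, PM1	VUS
1	FANCM	missense	P1255L	NA	NA	0	0.078	na	B	22	PM6, PM1, PM2	LP
1	FANCC	missense	E273Q	0.01759	NA	0.01	0.993	25.3	B	29	PM2, PM1, PP3	VUS
1	FANCC	frameshift	I121Tfs*7	NA	NA	NA	NA	32	NA	NA	PVS1, PM2, PM1	P
2	GDF9	missense	R454C	0.0041	0.004	0	1	28.8	B	180	PS1, PM2, PM1, PP3	LP
1	SPIDR	nonsense	S64*	NA	NA	NA	NA	26.9	NA	NA	PVS1, PM2, PM1	P
1	SPIDR	missense	R294K	0.00051	0.0031	1	0.047	17.5	B	26	PM2, PM1	VUS
1	POU5F1	missense	T116S	NA	NA	0.11	0.062	6.86	B	58.0	PM2, PP2	VUS
1	POU5F1	missense	P65R	NA	NA	0.0	0.495	11.43	B	103.0	PM6, PM2, PP2	VUS
1	SF1	missense	G517A	0.01772	NA	0.02	0.998	24.8	B	60	PM2, PP2, PP3	VUS
1	SF1	inframe_deletion	G39_P47del	NA	NA	NA	NA	19.52	NA	NA	PM2, PM4, PM6, PP2	LP
1	SOHLH1	inframe_deletion	G323del	0.01191	NA	NA	NA	11.44	NA	NA	PM6, PM2, PM4	LP
1	AMHR2	missense	G153R	NA	NA	0	1	25.7	B	125	PM6, PM1, PM2, PP3	LP
1	TP63	missense	R487C	0.00019	NA	0	0.997	31	D	180	PM2, PM1, PM5, PP2	LP
1	NANOS3	duplication	G171dup	NA	NA	NA	NA	14.8	NA	NA	PM1, PM2, PM4	LP
1	MRPS22	missense	V23L	NA	NA	0.02	0.043	9.9	B	32	PM1, PM2, PM6	LP
1	FOXL2	inframe_deletion	A234del	0.00107	NA	NA	NA	16.23	NA	NA	PM1, PM2, PM4	LP
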