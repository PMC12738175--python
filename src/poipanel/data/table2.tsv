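n_patients	gene	variant_type	aa_change	gnomad_nfe_af	eur_af_1kg	sift	polyphen	cadd_phred	mutation_taster	grantham	acmg_criteria	classification
1	ADAMTS1	missense	A806V	0.01759	NA	0.03	0.581	21.8	B	64	PP3, PM2, PM1	VUS
3	ADAMTS1	missense	T732I	0.00012	NA	0.05	0.18	20.7	B	89	PM2, PM1	VUS
2	ADAMTS1	missense	T514A	0.00012	0.001	0.01	0	18.49	B	58	PM2	VUS
3	POF1B	missense	R315C	0.00074	0.0013	0	1	31	B	180	PM2, PM1	VUS
1	BNC1	missense	G661R	NA	NA	0.31	0.007	14.9	B	125	PM2, PP2	VUS
1	BNC1	missense	E209K	0.02638	NA	0	1	29.3	D	56	PM2, PM5, PP2	VUS
1	CDKN1B	missense	S7C	NA	NA	0.0	1.0	28.1	B	112	PM2, PP3	VUS
1	CDKN1B	missense	P117S	0.06262	NA	0.02	0.167	18.56	D	74	PM2, PS3	VUS
1	WT1	missense	S325L	0.008814	NA	0	0.981	32	NA	145	PM2, PM1, PP3	VUS
1	WT1	missense	G37S	0.0000398	NA	0.01	0.008	15.6	B	56	PM2, PM1	VUS
1	MSH4	missense	S10L	NA	NA	0.31	0	11.6	B	145	PM2	VUS
1	MSH4	missense	L35I	0.0003181	0.002	0.03	0.041	8.8	B	5	PM2	VUS
1	WDR62	missense	S275L	0.07042	NA	0	1	29.5	B	145	PM2, PP3	VUS
1	WDR62	missense	Y336C	0.03519	NA	0.29	1	23.6	B	194	PM2, PP3	VUS
2	BRSK1	missense	P764A	0.005974	0.005	0.22	0	15.03	B	27	PM2, PP2	VUS
1	FANCG	missense	W122C	0.0001589	NA	0	1	26.9	B	215	PM2, PM1, PP3	VUS
1	SOHLH2	missense	S417L	0.000203	0.001	0	0.947	23	B	145	PM2, PM1, PP3	VUS
1	SYCE1	missense	R59Q	0.000229	NA	0.01	1	26.6	B	43	PM2, PM1	VUS
1	AGTR2	missense	G21V	0.004099	0.0026	na	na	8.7	B	109	PM2	VUS
1	FOXO1	missense	V564M	0.008816	NA	0.46	0.296	22.6	B	21	PM2	VUS
1	FOXO3	missense	A140S	0.0001551	NA	0.7	0.052	15.1	B	99	PM2, PM1	VUS
1	BBS9	missense	T865A	0.0005225	0.002	0.06	0.0	15.34	B	58	PM2, BP4	VUS
1	DUSP22	missense	A171T	0.02637	NA	0.85	0.0	11.68	B	58.0	BP4	VUS
1	LARS2	missense	S315L	0.01762	NA	0.64	0.002	20.5	B	145.0	PM2, PM1	VUS
1	NUPR1	missense	R74H	0.0000176	NA	0.18	0.76	23.4	B	29.0	PM2, PM, PP3	VUS
1	POLR3H	missense	V99I	0.02638	NA	0.02	0.544	32	D	29.0	PM2, PP3, PM1	VUS
1	SALL4	missense	G251R	0.008865	NA	0.2	0.661	8.9	B	125.0	PM2, PP2	VUS
1	DMC1	missense	A76T	NA	NA	0.04	0.104	24.6	D	58	PP3, PM2, PM1	VUS
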