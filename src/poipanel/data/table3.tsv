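patient_id	gene	chrom	variant_type	aa_change	classification
N52	DNAH5	5	missense	S3774P	LP
N52	DNAH5	5	missense	I3568T	VUS
N57	DNAH5	5	missense	Q2949E	VUS
NPMA_4	DNAH5	5	missense	N1420D	VUS
N63	DNAH5	5	missense	L1339R	VUS
N13	HK3	5	missense	P676S	VUS
N120	HK3	5	missense	Q600H	VUS
NPMA_11	HK3	5	missense	Q600H	VUS
N103	HK3	5	missense	I347T	LP
NPMA_7	HK3	5	missense	C237R	LP
N73	NOTCH2	1	missense	I1693T	VUS
N82_v1	NOTCH2	1	missense	R318L	VUS
NPMA_8	NOTCH2	1	missense	A147S	LP
N54	LAMC1	1	missense	R1011H	LP
NPMA_3	LAMC1	1	missense	R1011H	LP
N117	MSH4	1	missense	S10L	VUS
N102	MSH4	1	missense	L35I	VUS
NPMA_12	PCDH11X	X	missense	T790S	VUS
NPMA29	PCDH11X	X	missense	T790S	VUS
N58	POU5F1	6	missense	T116S	VUS
N2	POU5F1	6	missense	P65R	VUS
N118	BNC1	15	missense	G661R	VUS
N62	BNC1	15	missense	E209K	VUS
NPMA14	HSD17B4	5	missense	R658H	VUS
N105	ADAMTS1	21	missense	T732I	VUS
N104	AMHR2	12	missense	G153R	LP
NPMA17	AR	X	inframe_deletion	Q74_Q80del	LP
N113	FANCG	9	missense	W122C	VUS
NPMA_6	FANCM	14	missense	L57F	VUS
NPMA18	BRSK1	19	missense	P764A	VUS
N91	CDKN1B	12	missense	P117S	VUS
NPMA25	DMC1	22	missense	A76T	VUS
N15	DUSP22	6	missense	A171T	VUS
N70	MRPS22	3	missense	V23L	LP
N78	SPIDR	8	nonsense	S64*	P
N92	SYCE1	10	missense	R59Q	VUS
NPMA_49	WDR62	19	missense	Y336C	VUS
N109	WT1	11	missense	G37S	VUS
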