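patient_id	region	chrom	gene	change	length_bp	co_occurring	cadd_sv_phred	strvctvre	mvp
N38	10q26.3	10	SYCE1	gain	11349	NA	3.558	0.351	0.187
N58	10q26.3	10	SYCE1	gain	11349	POU5F1:T116S	NA	NA	NA
N75	10q26.3	10	SYCE1	gain	11349	PCDH11X:T790S;SALL4:G251R	NA	NA	NA
N85	10q26.3	10	SYCE1	gain	11349	AR:Q66_Q80del;FOXL2:A234del	NA	NA	NA
NPMA40	10q26.3	10	SYCE1	gain	11349	LAMC1:A1335S;AR:Q74_Q80del;FOXO3:A140S	NA	NA	NA
N47	6p25.3	6	DUSP22	loss	58438	NA	11.06	0.354	0.227
N57	6p25.3	6	DUSP22	gain	58438	DNAH5:Q2949E	13.79	0.264	0.154
N90	6p25.3	6	DUSP22	gain	58438	NA	NA	NA	NA
NPMA_3	6p25.3	6	DUSP22	gain	58438	LAMC1:R1011H	NA	NA	NA
NPMA_7	6p25.3	6	DUSP22	gain	58438	HK3:C237R	NA	NA	NA
N61	2q14.2	2	INHBB	loss	3890	NA	13.86	0.671	0.700
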