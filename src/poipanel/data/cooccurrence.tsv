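gene	variant_a	variant_b	n_patients
DNAH5	S3774P	I3568T	2
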