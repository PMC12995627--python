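probe_id	gene_symbol	list_rank	LumA	LumB_HER2neg	LumB_HER2pos	NonLum_HER2pos	TNBC
202859_x_at	CXCL8	1	3.08	3.33	5.76	7.65	8.18
211506_s_at	CXCL8	2	3.08	3.29	5.81	7.21	8.21
203684_s_at	BCL2	1	5.23	3.19	4.01	−3.19	−4.12
203685_at	BCL2	2	5.41	3.43	4.02	−3.21	−4.18
207004_at	BCL2	3	5.19	3.28	4.17	−3.43	−4.22
207005_s_at	BCL2	4	5.29	3.19	4.17	−4.19	−4.19
208478_s_at	BAX	1	3.18	4.55	5.98	9.12	9.87
211833_s_at	BAX	2	3.12	5.01	6.02	9.18	9.18
206011_at	CASP1	1	3.91	4.48	5.32	5.91	7.11
209970_x_at	CASP1	2	3.54	4.56	5.21	5.89	7.19
211366_x_at	CASP1	3	3.81	4.49	5.10	5.98	7.32
211367_s_at	CASP1	4	3.44	4.61	5.61	5.89	7.01
211368_s_at	CASP1	5	3.87	4.71	5.42	5.73	7.21
203984_s_at	CASP9	1	3.10	3.91	4.15	4.76	5.10
210775_x_at	CASP9	2	3.21	3.87	4.19	4.81	5.18
240437_at	CASP9	3	3.19	3.90	4.81	4.91	5.14
201746_at	TP53	1	3.11	3.41	5.91	6.19	7.89
211300_s_at	TP53	2	3.12	3.32	5.98	6.43	7.92
202284_s_at	CDKN1A	1	3.45	4.21	4.98	−4.18	−8.19
209112_at	CDKN1B	1	3.11	3.99	−3.14	−6.16	−17.55
203936_s_at	MMP9	1	3.19	3.87	4.56	9.19	12.91
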