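gene_symbol	mirna_id	target_score	LumA	LumB_HER2neg	LumB_HER2pos	NonLum_HER2pos	TNBC
CXCL8	hsa-miR-140-3p	94	3.08 ± 0.45*	3.08 ± 0.21*	3.33 ± 0.31*	5.76 ± 0.19*	7.65 ± 0.19*
BAX	hsa-miR-1843	90	3.18 ± 0.19*	3.18 ± 0.15*	4.45 ± 0.43*	5.98 ± 0.21*	9.12 ± 0.22*
CASP9	hsa-miR-124-3p	91	3.10 ± 0.23*	3.10 ± 0.19*	3.91 ± 0.12*	4.15 ± 0.19*	4.76 ± 0.29*
TP53	hsa-miR-300	89	3.11 ± 0.19*	3.11 ± 0.42*	3.41 ± 0.21*	5.91 ± 0.32*	6.19 ± 0.31*
CDKN1A	hsa-miR-608	95	3.45 ± 0.23*	3.45 ± 0.23*	4.21 ± 0.19*	4.98 ± 0.21*	−4.18 ± 0.19*
CDKN1B	hsa-miR-30d-3p	97	3.11 ± 0.19*	3.19 ± 0.18*	3.89 ± 0.32*	−3.14 ± 0.43*	−6.19 ± 0.76*
CDKN1B	hsa-miR-30a-3p	97	3.11 ± 0.18*	3.17 ± 0.18*	3.99 ± 0.21*	−3.14 ± 0.31*	−6.19 ± 0.54*
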