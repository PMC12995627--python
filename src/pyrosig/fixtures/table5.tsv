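gene_symbol	T1	T2	T3	T4	T5	T6
CXCL8	1.45 ± 0.18*	2.10 ± 0.25*	1.90 ± 0.22*	1.35 ± 0.16*	1.10 ± 0.12	1.02 ± 0.10
BCL2	1.05 ± 0.09	1.10 ± 0.11*	1.08 ± 0.10*	1.03 ± 0.09	1.00 ± 0.08	0.98 ± 0.08
BAX	1.30 ± 0.14	1.80 ± 0.20*	1.75 ± 0.19*	1.30 ± 0.15*	1.10 ± 0.11	1.00 ± 0.10
CASP1	1.35 ± 0.15	1.95 ± 0.21*	1.85 ± 0.20*	1.40 ± 0.16*	1.12 ± 0.12	1.03 ± 0.10
CASP9	1.25 ± 0.13	1.70 ± 0.18*	1.65 ± 0.17*	1.28 ± 0.14	1.08 ± 0.11	1.01 ± 0.09
TP53	1.20 ± 0.12	1.55 ± 0.17	1.50 ± 0.16*	1.25 ± 0.13	1.05 ± 0.10	1.00 ± 0.09
CDKN1A	1.15 ± 0.12	1.35 ± 0.15	1.30 ± 0.14	1.10 ± 0.12	1.02 ± 0.10	0.98 ± 0.09
CDKN1B	1.10 ± 0.11	1.25 ± 0.13	1.22 ± 0.13	1.08 ± 0.11	1.00 ± 0.09	0.98 ± 0.08
MMP9	1.40 ± 0.16*	2.00 ± 0.23*	1.85 ± 0.21*	1.45 ± 0.17*	1.15 ± 0.13	1.05 ± 0.11
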