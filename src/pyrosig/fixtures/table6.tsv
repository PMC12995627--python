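protein	unit	T0	T1	T2	T3	T4	T5	T6
CXCL8	pg/mL	65.2 ± 8.1	92.4 ± 10.5*	138.7 ± 14.9*	125.3 ± 13.8*	88.6 ± 9.7	70.9 ± 8.4*	66.3 ± 7.9
BCL2	ng/mL	2.8 ± 0.3	3.0 ± 0.3	3.2 ± 0.4*	3.1 ± 0.3*	2.9 ± 0.3*	2.8 ± 0.3*	2.7 ± 0.3*
BAX	ng/mL	1.4 ± 0.2	1.9 ± 0.2*	2.6 ± 0.3*	2.5 ± 0.3*	1.9 ± 0.2	1.6 ± 0.2*	1.4 ± 0.2*
CASP1	ng/mL	0.18 ± 0.03	0.32 ± 0.04*	0.52 ± 0.06*	0.49 ± 0.05*	0.30 ± 0.04*	0.22 ± 0.03*	0.19 ± 0.03*
CASP9	ng/mL	1.10 ± 0.14	1.55 ± 0.18*	2.20 ± 0.25*	2.05 ± 0.23*	1.50 ± 0.18*	1.25 ± 0.15*	1.12 ± 0.14*
P53	pg/mL	95.3 ± 9.6	130.8 ± 12.7*	178.4 ± 16.9*	169.2 ± 15.8*	122.7 ± 11.3*	102.9 ± 10.1*	96.5 ± 9.4*
CDKN1A	ng/mL	0.95 ± 0.10	1.20 ± 0.13*	1.40 ± 0.15*	1.35 ± 0.14*	1.05 ± 0.11*	0.97 ± 0.10*	0.94 ± 0.09*
CDKN1B	ng/mL	1.05 ± 0.11	1.25 ± 0.13*	1.45 ± 0.16*	1.40 ± 0.15*	1.15 ± 0.12**	1.03 ± 0.11*	1.00 ± 0.10*
MMP9	pg/mL	260.5 ± 28.7	340.9 ± 35.1*	520.6 ± 49.8*	485.3 ± 45.7*	330.1 ± 32.2*	280.9 ± 29.4*	265.7 ± 27.9*
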