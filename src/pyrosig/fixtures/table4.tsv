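protein	unit	Control	LumA	LumB_HER2neg	LumB_HER2pos	NonLum_HER2pos	TNBC
CXCL8	pg/mL	82.4 ± 9.8	152.7 ± 14.2*	184.9 ± 16.1*	362.5 ± 22.4*	918.3 ± 41.7*	1248.6 ± 55.2*
BCL2	ng/mL	5.3 ± 0.6	24.8 ± 2.1*	17.6 ± 1.9*	20.9 ± 1.4*	3.2 ± 0.4*	2.1 ± 0.3*
BAX	ng/mL	2.2 ± 0.3	5.4 ± 0.5*	9.3 ± 0.9*	15.7 ± 1.2*	34.4 ± 2.7*	46.8 ± 3.8*
CASP1	ng/mL	0.28 ± 0.04	1.19 ± 0.09*	2.11 ± 0.18*	3.62 ± 0.24*	6.73 ± 0.41*	10.84 ± 0.69*
CASP9	ng/mL	1.47 ± 0.17	4.12 ± 0.38*	6.48 ± 0.53*	8.23 ± 0.49*	15.29 ± 0.91*	20.88 ± 1.34*
P53	pg/mL	118.3 ± 10.2	298.4 ± 21.6*	352.9 ± 24.1*	701.8 ± 33.5*	1134.2 ± 52.6*	1622.4 ± 68.3*
CDKN1A	ng/mL	1.18 ± 0.12	7.83 ± 0.71*	10.21 ± 0.89*	11.92 ± 0.97*	3.14 ± 0.29*	1.07 ± 0.11*
CDKN1B	ng/mL	1.36 ± 0.15	6.14 ± 0.53*	8.31 ± 0.72*	2.18 ± 0.19*	1.04 ± 0.10*	0.79 ± 0.08*
MMP9	pg/mL	310.4 ± 34.1	628.9 ± 51.3*	812.7 ± 62.8*	1432.5 ± 98.6*	5128.7 ± 243.9*	8234.6 ± 387.5*
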