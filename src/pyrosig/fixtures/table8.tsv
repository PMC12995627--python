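subtype	IAS
LumA	3.35
LumB_HER2neg	3.92
LumB_HER2pos	5.15
NonLum_HER2pos	7.00
TNBC	8.41
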