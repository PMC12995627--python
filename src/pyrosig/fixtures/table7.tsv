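subtype	PI
LumA	−0.67
LumB_HER2neg	0.13
LumB_HER2pos	3.33
NonLum_HER2pos	11.65
TNBC	18.46
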