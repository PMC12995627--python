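gene_symbol	forward	reverse
CXCL8	CAGCCAACAGGTGAGAATGA	TTGAAGGATGTTCCCAGAGG
BCL2	GATTGTGGCCTTCTTTGAG	GTTCCACAAAGGCATCC
BAX	CCTGTGCACCAAGGTGCCGGAACT	CCACCCTGGTCTTGGATCCAGCCC
CASP1	CAACTACAGAAGAGTTTGAGG	AACATTATCTGGTGTGGAAG
CASP9	CTCTACTTTCCCAGGTTTTG	TTTCACCGAAACAGCATTAG
TP53	ACCTATGGAAACTACTTCCTG	ACCATTGTTCAATATCGTCC
CDKN1A	CAGCATGACAGATTTCTACC	CAGGGTATGTACATGAGGAG
CDKN1B	AACCGACGATTCTTCTACTC	TGTTTACGTTTGACGTCTTC
MMP9	GAGTTCCCGGAGTGAGTTGA	AAAGGTGAGAAGAGAGGGCC
ACTB	TCACCCACACTGTGCCCATCTACGA	CAGCGGAACCGCTCATTGCCAATGG
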